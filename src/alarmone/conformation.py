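"""Nucleotide conformational analysis.

Implements the classical torsion-angle description of a nucleotide:

* the glycosidic torsion chi (O4'-C1'-N9-C4) with syn/anti classification
  (anti iff chi mod 360 in [90, 270), boundary 90 -> anti, 270 -> syn),
* the backbone torsion gamma (O5'-C5'-C4'-C3'),
* the five endocyclic ribose torsions nu0..nu4 and the Altona-Sundaralingam
  pseudorotation parameters: phase angle P and maximum puckering amplitude
  nu_max, with the ten 36-degree pucker classes (C3'-endo at [0, 36), then
  C4'-exo, O4'-endo, C1'-exo, C2'-endo, C3'-exo, C4'-endo, O4'-exo,
  C1'-endo, C2'-exo),

plus conformer-ensemble descriptors (RMSF, RMSD, radius of gyration,
intramolecular hydrogen bonds, Shrake-Rupley SASA) and least-squares
(Kabsch) superposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure_io import (
    Atom,
    LigandInstance,
    StructureModel,
    ligand_atom_flags,
    parse_pdb,
)

__all__ = [
    "TorsionSet",
    "PuckerResult",
    "GlycosidicClass",
    "ConformerEnsemble",
    "EnsembleSummary",
    "PUCKER_CLASSES",
    "VDW_RADII",
    "dihedral",
    "compute_torsions",
    "ideal_ring_torsions",
    "pseudorotation",
    "classify_glycosidic",
    "torsion_distribution",
    "rmsf",
    "radius_of_gyration",
    "sasa",
    "count_intramolecular_hbonds",
    "kabsch_superpose",
    "ensemble_summary",
    "analyze_ligand",
    "analyze_torsion_table",
    "read_torsion_table",
    "write_torsion_table",
]

#: pucker class names by 36-degree bin of P, starting at [0, 36)
PUCKER_CLASSES = (
    "C3'-endo", "C4'-exo", "O4'-endo", "C1'-exo", "C2'-endo",
    "C3'-exo", "C4'-endo", "O4'-exo", "C1'-endo", "C2'-exo",
)

#: Bondi van der Waals radii (Å); metals use ionic-ish working values
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "SE": 1.90,
    "MG": 1.73, "MN": 1.73, "ZN": 1.39, "NA": 2.27, "K": 2.75, "CA": 2.31,
}

_AS_DENOM = 2.0 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))

#: torsion definitions over the ribose ring O4'-C1'-C2'-C3'-C4'
NU_ATOMS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)
CHI_ATOMS = ("O4'", "C1'", "N9", "C4")
GAMMA_ATOMS = ("O5'", "C5'", "C4'", "C3'")


def wrap_degrees(angle) -> np.ndarray | float:
    """Wrap angle(s) into (-180, 180]."""
    a = np.mod(np.asarray(angle, dtype=float), 360.0)
    a = np.where(a > 180.0, a - 360.0, a)
    return float(a) if np.isscalar(angle) or np.ndim(angle) == 0 else a


@dataclass(frozen=True)
class TorsionSet:
    """Glycosidic, backbone and endocyclic torsions of one nucleotide (degrees)."""

    chi: float
    gamma: float
    nu: tuple[float, float, float, float, float]


@dataclass(frozen=True)
class PuckerResult:
    """Pseudorotation phase P in [0, 360), amplitude nu_max >= 0, pucker class."""

    P: float
    nu_max: float
    pucker_class: str
    hemisphere: Literal["north", "south"]


@dataclass(frozen=True)
class GlycosidicClass:
    label: Literal["syn", "anti"]


# ---------------------------------------------------------------------------
# torsions


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle in degrees, IUPAC sign convention, range (-180, 180].

    Looking down the p2->p3 bond, a clockwise rotation of p3-p4 relative to
    p1-p2 is positive.  The value is invariant under order reversal
    (p1..p4 and p4..p1 give the same angle); mirror reflection negates it.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("dihedral undefined: three consecutive points are collinear")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = math.degrees(math.atan2(np.dot(m, n2), np.dot(n1, n2)))
    return 180.0 if angle <= -180.0 + 1e-12 else angle


def _torsion_from_ligand(ligand: LigandInstance, atoms: Sequence[str], label: str) -> float:
    try:
        pts = ligand.coords_of(atoms)
    except KeyError as exc:
        raise ValueError(f"cannot compute torsion {label}: missing atom {exc.args[0]}") from None
    return dihedral(*pts)


def compute_torsions(ligand: LigandInstance) -> TorsionSet:
    """Compute chi, gamma and nu0..nu4 from ligand coordinates."""
    chi = _torsion_from_ligand(ligand, CHI_ATOMS, "chi")
    gamma = _torsion_from_ligand(ligand, GAMMA_ATOMS, "gamma")
    nu = tuple(_torsion_from_ligand(ligand, atoms, f"nu{j}")
               for j, atoms in enumerate(NU_ATOMS))
    return TorsionSet(chi=chi, gamma=gamma, nu=nu)


def ideal_ring_torsions(P: float, nu_max: float) -> tuple[float, ...]:
    """Ideal endocyclic torsions nu_j = nu_max * cos(P + 144 deg * (j - 2))."""
    return tuple(nu_max * math.cos(math.radians(P + 144.0 * (j - 2))) for j in range(5))


def pseudorotation(nu: Sequence[float]) -> PuckerResult:
    """Altona-Sundaralingam pseudorotation analysis of five endocyclic torsions.

    tan P = [(nu4 + nu1) - (nu3 + nu0)] / [2 nu2 (sin 36 + sin 72)], with
    180 degrees added when nu2 < 0, P normalized to [0, 360), and
    nu_max = nu2 / cos P.  Near P = 90/270 (nu2 ~ 0) the amplitude is
    recovered by a least-squares fit of the ideal cosine model.
    """
    nu = [float(v) for v in nu]
    if len(nu) != 5:
        raise ValueError("expected five endocyclic torsions")
    if all(abs(v) < 1e-12 for v in nu):
        raise ValueError("planar ring: all endocyclic torsions are zero")
    nu0, nu1, nu2, nu3, nu4 = nu
    numerator = (nu4 + nu1) - (nu3 + nu0)
    if abs(nu2) < 1e-9:
        P = 90.0 if numerator > 0 else 270.0
        phases = np.radians(P + 144.0 * (np.arange(5) - 2))
        c = np.cos(phases)
        nu_max = float(np.dot(nu, c) / np.dot(c, c))
    else:
        P = math.degrees(math.atan(numerator / (nu2 * _AS_DENOM)))
        if nu2 < 0:
            P += 180.0
        P %= 360.0
        nu_max = nu2 / math.cos(math.radians(P))
    pucker = PUCKER_CLASSES[int(P // 36.0) % 10]
    hemisphere = "north" if (P < 90.0 or P >= 270.0) else "south"
    return PuckerResult(P=P, nu_max=nu_max, pucker_class=pucker, hemisphere=hemisphere)


def classify_glycosidic(chi: float) -> GlycosidicClass:
    """syn/anti classification: anti iff chi mod 360 in [90, 270)."""
    if not math.isfinite(chi):
        raise ValueError("chi must be finite")
    return GlycosidicClass("anti" if 90.0 <= chi % 360.0 < 270.0 else "syn")


def torsion_distribution(series: Sequence[float], bin_width: float = 10.0) -> pd.Series:
    """Percentage frequency histogram of torsion angles over (-180, 180].

    Bins are left-open/right-closed; the index holds bin centers; values sum
    to 100.  ``bin_width`` must divide 360.
    """
    values = np.asarray(series, dtype=float)
    if values.size == 0:
        raise ValueError("empty torsion series")
    n_bins = 360.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin width {bin_width} does not divide 360")
    n_bins = int(round(n_bins))
    wrapped = wrap_degrees(values)
    idx = np.ceil((wrapped + 180.0) / bin_width).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    centers = -180.0 + bin_width * (np.arange(n_bins) + 0.5)
    return pd.Series(100.0 * counts / values.size, index=centers, name="percent")


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class ConformerEnsemble:
    """Ordered coordinate sets over a fixed atom list (shape F x N x 3, Å)."""

    coords: np.ndarray
    atoms: list[Atom] | None = None
    labels: list | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.atoms is not None and len(self.atoms) != self.coords.shape[1]:
            raise ValueError("atom list length does not match coordinate columns")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_models(cls, models: Sequence[StructureModel]) -> "ConformerEnsemble":
        ref = models[0]
        names = [(a.chain_id, a.residue_seq, a.name) for a in ref.atoms]
        for m in models[1:]:
            if [(a.chain_id, a.residue_seq, a.name) for a in m.atoms] != names:
                raise ValueError("conformers must share an identical atom list and order")
        return cls(coords=np.stack([m.coords for m in models]), atoms=list(ref.atoms))

    @classmethod
    def from_pdb(cls, source) -> "ConformerEnsemble":
        return cls.from_models(parse_pdb(source))


@dataclass
class EnsembleSummary:
    """Per-frame/per-atom descriptors of a conformer ensemble."""

    rmsf: np.ndarray
    rmsd_series: np.ndarray
    rgyr_series: np.ndarray
    intra_hb_series: np.ndarray | None = None
    sasa_series: np.ndarray | None = None


def rmsf(ens: ConformerEnsemble, reference: Literal["mean", "frame0"] = "mean",
         superpose: bool = False) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Å) about the mean or first frame.

    By default the fluctuation is computed on the supplied coordinates with no
    superposition (ensembles from simulation engines are typically already
    centred); set ``superpose`` to rigidly align every frame on frame 0 first.
    """
    if ens.n_frames < 2:
        raise ValueError("RMSF needs at least two conformers")
    coords = ens.coords
    if superpose:
        aligned = [coords[0]]
        for frame in coords[1:]:
            R, t, _ = kabsch_superpose(frame, coords[0])
            aligned.append(frame @ R.T + t)
        coords = np.stack(aligned)
    ref = coords.mean(axis=0) if reference == "mean" else coords[0]
    return np.sqrt(((coords - ref) ** 2).sum(axis=2).mean(axis=0))


def radius_of_gyration(coords, masses=None) -> float:
    """Mass-weighted radius of gyration (Å); unit masses by default."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if coords.shape[0] == 0:
        raise ValueError("radius of gyration of an empty atom set")
    m = np.ones(coords.shape[0]) if masses is None else np.asarray(masses, dtype=float)
    com = (coords * m[:, None]).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((coords - com) ** 2).sum(axis=1)).sum() / m.sum()))


def _golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-section spiral)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(atoms, radii: dict[str, float] | None = None, probe: float = 1.4,
         n_points: int = 960) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area (per-atom and total, Å^2).

    ``atoms`` is either a sequence of :class:`Atom` or a ``(coords, elements)``
    pair.  The sphere point set is a fixed golden-section spiral, so results
    are deterministic for a given ``n_points``.
    """
    if isinstance(atoms, tuple):
        coords, elements = atoms
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        elements = [e.upper() for e in elements]
    else:
        coords = np.array([a.coords for a in atoms], dtype=float)
        elements = [a.element.upper() for a in atoms]
    table = VDW_RADII if radii is None else radii
    try:
        r = np.array([table[e] for e in elements], dtype=float) + probe
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius for element {exc.args[0]!r}") from None
    unit = _golden_spiral_points(n_points)
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    per_atom = np.zeros(n)
    for i in range(n):
        neighbors = np.where((d[i] < r[i] + r) & (np.arange(n) != i))[0]
        pts = coords[i] + r[i] * unit
        if neighbors.size:
            dist2 = ((pts[:, None, :] - coords[neighbors][None, :, :]) ** 2).sum(axis=2)
            accessible = ~(dist2 < (r[neighbors] ** 2)[None, :]).any(axis=1)
        else:
            accessible = np.ones(n_points, dtype=bool)
        per_atom[i] = 4.0 * math.pi * r[i] ** 2 * accessible.mean()
    return per_atom, float(per_atom.sum())


def _bond_graph(coords: np.ndarray, elements: Sequence[str]) -> list[list[int]]:
    """Covalent bonds inferred from distances (generic 1.85 Å, 1.95 Å at P/S)."""
    n = coords.shape[0]
    adj: list[list[int]] = [[] for _ in range(n)]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    for i in range(n):
        for j in range(i + 1, n):
            cut = 1.95 if ("P" in (elements[i], elements[j]) or
                           "S" in (elements[i], elements[j])) else 1.85
            if 0.4 < d[i, j] <= cut:
                adj[i].append(j)
                adj[j].append(i)
    return adj


def _bond_separation(adj: list[list[int]], start: int, stop_at: int = 4) -> dict[int, int]:
    dist = {start: 0}
    frontier = [start]
    depth = 0
    while frontier and depth < stop_at:
        depth += 1
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = depth
                    nxt.append(v)
        frontier = nxt
    return dist


def count_intramolecular_hbonds(ligand: LigandInstance, criteria=None) -> int:
    """Donor-acceptor pairs within hydrogen-bond geometry inside one conformer.

    Pairs separated by fewer than three covalent bonds are excluded.  The
    donor angle uses the heavy-atom antecedent proxy (no hydrogens required).
    """
    from .interactions import InteractionCriteria, donor_angle_proxy

    criteria = criteria or InteractionCriteria()
    flags = ligand_atom_flags(ligand)
    atoms = ligand.atoms
    coords = np.array([a.coords for a in atoms])
    elements = [a.element.upper() for a in atoms]
    adj = _bond_graph(coords, elements)
    count = 0
    for i, ai in enumerate(atoms):
        if not flags[ai.name].donor:
            continue
        sep = _bond_separation(adj, i, stop_at=3)
        for j, aj in enumerate(atoms):
            if i == j or not flags[aj.name].acceptor:
                continue
            if sep.get(j, 99) < 3:
                continue
            dist = float(np.linalg.norm(coords[i] - coords[j]))
            if not criteria.hbond_dist[0] <= dist <= criteria.hbond_dist[1]:
                continue
            angle = donor_angle_proxy(coords[i], [coords[k] for k in adj[i]], coords[j])
            if angle is None or angle >= criteria.hbond_angle[0]:
                count += 1
    return count


def kabsch_superpose(mobile, target) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of matched coordinates (proper rotation only).

    Returns ``(R, t, rmsd)`` with the mobile set mapped by ``x @ R.T + t``.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValueError("superposition needs >= 3 matched atom pairs")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    m0, t0 = mobile - mc, target - tc
    if np.linalg.matrix_rank(np.vstack([m0, t0]), tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinates: superposition ill-defined")
    rot, _ = Rotation.align_vectors(t0, m0)
    R = rot.as_matrix()
    t = tc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(((moved - target) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def ensemble_summary(ens: ConformerEnsemble, reference: Literal["mean", "frame0"] = "frame0",
                     include_sasa: bool = True) -> EnsembleSummary:
    """RMSF, per-frame RMSD/rGyr and (when atoms are known) intraHB and SASA series."""
    ref = ens.coords.mean(axis=0) if reference == "mean" else ens.coords[0]
    rmsd_series = np.sqrt(((ens.coords - ref) ** 2).sum(axis=2).mean(axis=1))
    rgyr_series = np.array([radius_of_gyration(f) for f in ens.coords])
    intra = sasa_series = None
    if ens.atoms is not None:
        lig_template = LigandInstance(
            ligand_code="G4P", atoms=list(ens.atoms),
            completeness={"frames": True})
        intra = np.empty(ens.n_frames)
        for f, frame in enumerate(ens.coords):
            frame_atoms = [Atom(a.serial, a.name, a.element, a.residue_name, a.residue_seq,
                                a.chain_id, xyz, a.occupancy, a.is_hetero)
                           for a, xyz in zip(ens.atoms, frame)]
            lig = LigandInstance(ligand_code=lig_template.ligand_code, atoms=frame_atoms)
            intra[f] = count_intramolecular_hbonds(lig)
        if include_sasa:
            elements = [a.element for a in ens.atoms]
            sasa_series = np.array([sasa((frame, elements))[1] for frame in ens.coords])
    return EnsembleSummary(rmsf=rmsf(ens), rmsd_series=rmsd_series,
                           rgyr_series=rgyr_series, intra_hb_series=intra,
                           sasa_series=sasa_series)


# ---------------------------------------------------------------------------
# tabular interface


TORSION_COLUMNS = ["id", "chi", "gamma", "nu0", "nu1", "nu2", "nu3", "nu4",
                   "P", "nu_max", "pucker_class", "glycosidic_class"]


def analyze_ligand(ligand: LigandInstance, ligand_id: str = "") -> dict:
    """One torsion-table row (chi, gamma, nu0..nu4, P, nu_max, classes) from coordinates."""
    ts = compute_torsions(ligand)
    pk = pseudorotation(ts.nu)
    return {
        "id": ligand_id or f"{ligand.ligand_code}_{ligand.chain_id}{ligand.residue_seq}",
        "chi": ts.chi, "gamma": ts.gamma,
        **{f"nu{j}": ts.nu[j] for j in range(5)},
        "P": pk.P, "nu_max": pk.nu_max, "pucker_class": pk.pucker_class,
        "glycosidic_class": classify_glycosidic(ts.chi).label,
    }


def analyze_torsion_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add P, nu_max, pucker and syn/anti columns to a torsion table.

    The input needs columns nu0..nu4 and (optionally) chi, gamma, id.
    """
    rows = []
    for _, row in df.iterrows():
        nu = [row[f"nu{j}"] for j in range(5)]
        pk = pseudorotation(nu)
        rec = {"id": row.get("id", ""), "chi": row.get("chi", np.nan),
               "gamma": row.get("gamma", np.nan),
               **{f"nu{j}": nu[j] for j in range(5)},
               "P": pk.P, "nu_max": pk.nu_max, "pucker_class": pk.pucker_class}
        rec["glycosidic_class"] = (classify_glycosidic(row["chi"]).label
                                   if "chi" in row and np.isfinite(row["chi"]) else "")
        rows.append(rec)
    return pd.DataFrame(rows, columns=TORSION_COLUMNS)


def read_torsion_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_torsion_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.2f")
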