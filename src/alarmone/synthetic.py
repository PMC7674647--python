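"""Ground-truth synthetic fixtures: nucleotides, binding sites, ensembles.

Everything the analysis stages consume can be generated here with known
truth: ppGpp/pppGpp ligands built at prescribed pseudorotation (P, nu_max)
and glycosidic/backbone angles (chi, gamma); toy binding sites with one
planted contact per interaction category at controlled geometry; glycosidic
torsion ensembles drawn from von Mises mixtures with known syn/anti weights;
and an annotated corpus whose per-class interaction patterns mirror the
published class signatures (tyrosine stacking and arginine salt bridges in
synthetases and nucleotide-metabolic enzymes, neither stacking nor metals
in GTPases).

Output is deterministic for a fixed seed (byte-identical PDB text).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .aggregation import ComplexAnnotation
from .conformation import (
    VDW_RADII,
    compute_torsions,
    dihedral,
    ideal_ring_torsions,
    pseudorotation,
)
from .interactions import InteractionCriteria
from .structure_io import (
    Atom,
    GUANINE_6RING,
    LigandInstance,
    StructureModel,
    flags_for,
    write_pdb,
)

__all__ = [
    "LigandSpec",
    "PlantedContact",
    "SiteSpec",
    "EnsembleSpec",
    "build_ribose",
    "build_nucleotide",
    "build_site",
    "build_water_bridge_site",
    "sample_chi_ensemble",
    "build_corpus",
    "write_corpus",
    "nine_category_contacts",
    "CLASS_RECIPES",
    "place_atom",
]


# ---------------------------------------------------------------------------
# internal-coordinate placement


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D bonded to c with |cD| = bond, angle(b,c,D) = angle and
    dihedral(a,b,c,D) = torsion (natural extension reference frame)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.sin(ang) * math.cos(tor),
                        -bond * math.sin(ang) * math.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# ribose ring construction (inverse pseudorotation problem)

RING_NAMES = ("O4'", "C1'", "C2'", "C3'", "C4'")
#: ring bond targets in Å following the ring order (O4'-C1', C1'-C2', ...)
RING_BONDS = (1.415, 1.527, 1.525, 1.525, 1.452)
#: indices of the atoms of nu_j within RING_NAMES
_NU_INDEX = ((4, 0, 1, 2), (0, 1, 2, 3), (1, 2, 3, 4), (2, 3, 4, 0), (3, 4, 0, 1))
_RING_ANGLE_TARGET = 104.0  # soft target for internal ring angles (degrees)


def _ring_residuals(x: np.ndarray, nu_targets: Sequence[float]) -> np.ndarray:
    pts = x.reshape(5, 3)
    res = []
    for i in range(5):
        d = np.linalg.norm(pts[(i + 1) % 5] - pts[i])
        res.append(20.0 * (d - RING_BONDS[i]))
    for j, idx in enumerate(_NU_INDEX):
        tau = dihedral(*(pts[k] for k in idx))
        delta = (tau - nu_targets[j] + 180.0) % 360.0 - 180.0
        res.append(0.25 * delta)
    for i in range(5):
        v1 = pts[(i - 1) % 5] - pts[i]
        v2 = pts[(i + 1) % 5] - pts[i]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = math.degrees(math.acos(min(1.0, max(-1.0, cosang))))
        res.append(0.02 * (ang - _RING_ANGLE_TARGET))
    return np.asarray(res)


def build_ribose(P_target: float, nu_max_target: float, seed: int = 0,
                 tol_deg: float = 2.0) -> dict[str, np.ndarray]:
    """Closed five-membered ribose ring hitting the requested pucker.

    The ring starts as a planar pentagon with an out-of-plane displacement
    wave and is refined by least squares against the ideal endocyclic
    torsions nu_j = nu_max cos(P + 144 (j - 2)); the measured pseudorotation
    of the result is within ``tol_deg`` of the request or an error is raised.
    """
    if not 5.0 < nu_max_target < 60.0:
        raise ValueError("nu_max target must lie in (5, 60) degrees (non-planar ring)")
    nu_targets = ideal_ring_torsions(P_target % 360.0, nu_max_target)
    radius = 1.49 / (2.0 * math.sin(math.pi / 5.0))
    last = None
    for phase_step in range(10):  # phase 0 converges in practice; others are fallback
        phase = math.radians(36.0 * phase_step)
        x0 = []
        for k in range(5):
            theta = 2.0 * math.pi * k / 5.0
            z = 0.012 * nu_max_target * math.cos(phase + 4.0 * math.pi * k / 5.0)
            x0.extend([radius * math.cos(theta), radius * math.sin(theta), z])
        sol = least_squares(_ring_residuals, np.array(x0), args=(nu_targets,),
                            xtol=1e-10, ftol=1e-10, max_nfev=800)
        pts = sol.x.reshape(5, 3)
        measured = [dihedral(*(pts[k] for k in idx)) for idx in _NU_INDEX]
        pk = pseudorotation(measured)
        dP = abs((pk.P - P_target + 180.0) % 360.0 - 180.0)
        last = (pk, sol.cost)
        if dP <= tol_deg and abs(pk.nu_max - nu_max_target) <= tol_deg:
            return {name: pts[i].copy() for i, name in enumerate(RING_NAMES)}
    pk, cost = last
    raise RuntimeError(
        f"ring closure did not converge: requested P={P_target:.2f}, "
        f"nu_max={nu_max_target:.2f}; measured P={pk.P:.2f}, nu_max={pk.nu_max:.2f} "
        f"(cost {cost:.3g})")


# ---------------------------------------------------------------------------
# guanine template (planar fused 5/6 rings, uniform bond length)


def _purine_template(side: float = 1.38) -> dict[str, np.ndarray]:
    """Planar guanine template with N9 at the origin and C4 on +x.

    Regular fused pentagon/hexagon sharing the C4-C5 edge; exocyclic O6 and
    N2 on the external angle bisectors.  Adequate idealized geometry for
    typing, census and stacking work.
    """

    def polygon(n: int, p0: np.ndarray, p1: np.ndarray, left: bool) -> list[np.ndarray]:
        # walk a regular n-gon from edge p0->p1, turning left or right
        pts = [p0, p1]
        ext = math.radians(360.0 / n) * (1.0 if left else -1.0)
        direction = math.atan2(p1[1] - p0[1], p1[0] - p0[0])
        for _ in range(n - 2):
            direction += ext
            prev = pts[-1]
            pts.append(prev + side * np.array([math.cos(direction), math.sin(direction)]))
        return pts

    n9 = np.array([0.0, 0.0])
    c4 = np.array([side, 0.0])
    # pentagon N9 -> C4 -> C5 -> N7 -> C8, turning left (body in y > 0)
    pent = polygon(5, n9, c4, left=True)
    _, _, c5, n7, c8 = pent
    # hexagon C4 -> C5 walks the shared edge; body on the opposite side of N9
    hexa = polygon(6, c4, c5, left=False)
    _, _, c6, n1, c2, n3 = hexa

    def bisector_sub(center: np.ndarray, nb1: np.ndarray, nb2: np.ndarray,
                     bond: float) -> np.ndarray:
        u = (center - nb1) / np.linalg.norm(center - nb1)
        v = (center - nb2) / np.linalg.norm(center - nb2)
        w = u + v
        return center + bond * w / np.linalg.norm(w)

    o6 = bisector_sub(c6, c5, n1, 1.24)
    n2 = bisector_sub(c2, n1, n3, 1.34)
    coords2d = {"N9": n9, "C4": c4, "C5": c5, "N7": n7, "C8": c8,
                "C6": c6, "N1": n1, "C2": c2, "N3": n3, "O6": o6, "N2": n2}
    return {k: np.array([v[0], v[1], 0.0]) for k, v in coords2d.items()}


_PURINE = _purine_template()


# ---------------------------------------------------------------------------
# full nucleotide


@dataclass(frozen=True)
class LigandSpec:
    """Target conformation for a generated (p)ppGpp ligand (degrees)."""

    P_target: float = 188.23
    nu_max_target: float = 36.24
    chi_target: float = -99.58
    gamma_target: float = -172.55
    include_gamma_phosphate: bool = False

    def __post_init__(self) -> None:
        if not 5.0 < self.nu_max_target < 60.0:
            raise ValueError("nu_max_target must lie in (5, 60)")
        for name in ("P_target", "chi_target", "gamma_target"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def ligand_code(self) -> str:
        return "C1Z" if self.include_gamma_phosphate else "G4P"


def _element_of(name: str) -> str:
    return "P" if name.startswith("P") else name[0]


def build_nucleotide(spec: LigandSpec, seed: int = 0,
                     chain_id: str = "A", residue_seq: int = 1,
                     serial_start: int = 1) -> tuple[LigandInstance, str]:
    """Build a complete ppGpp/pppGpp ligand at the prescribed conformation.

    Returns the :class:`LigandInstance` and its PDB text.  The glycosidic
    angle is honoured to better than 0.5 degrees and the ring pucker to the
    ring-closure tolerance (2 degrees).
    """
    ring = build_ribose(spec.P_target, spec.nu_max_target, seed=seed)
    nu = [dihedral(*(ring[n] for n in names)) for names in (
        ("C4'", "O4'", "C1'", "C2'"), ("O4'", "C1'", "C2'", "C3'"),
        ("C1'", "C2'", "C3'", "C4'"), ("C2'", "C3'", "C4'", "O4'"),
        ("C3'", "C4'", "O4'", "C1'"))]
    coords = dict(ring)

    # exocyclic ring substituents: base on the beta face, O2'/O3' on alpha
    coords["N9"] = place_atom(coords["C4'"], coords["O4'"], coords["C1'"],
                              1.47, 108.0, nu[0] + 122.0)
    coords["O2'"] = place_atom(coords["O4'"], coords["C1'"], coords["C2'"],
                               1.41, 110.0, nu[1] - 122.0)
    coords["O3'"] = place_atom(coords["O4'"], coords["C4'"], coords["C3'"],
                               1.42, 110.0, nu[3] - 122.0)
    coords["C5'"] = place_atom(coords["C2'"], coords["C3'"], coords["C4'"],
                               1.51, 110.0, nu[3] + 122.0)

    # guanine: C4 fixes chi, C8 on the opposite half-plane (sp2 N9), then the
    # rigid planar template is mapped onto the (N9, C4, C8) frame
    coords["C4"] = place_atom(coords["O4'"], coords["C1'"], coords["N9"],
                              1.38, 127.0, spec.chi_target)
    coords["C8"] = place_atom(coords["O4'"], coords["C1'"], coords["N9"],
                              1.38, 125.0, spec.chi_target + 180.0)
    origin = coords["N9"]
    ex = coords["C4"] - origin
    ex /= np.linalg.norm(ex)
    w = coords["C8"] - origin
    ey = w - np.dot(w, ex) * ex
    ey /= np.linalg.norm(ey)
    t_c8 = _PURINE["C8"]
    sign = 1.0 if t_c8[1] > 0 else -1.0
    for name, txyz in _PURINE.items():
        if name in ("N9", "C4", "C8"):
            continue
        coords[name] = origin + txyz[0] * ex + sign * txyz[1] * ey

    # 5' phosphate chain: C5'-O5'-PA(-O1A,-O2A)-O3A-PB(-O1B,-O2B,-O3B)[-PG...]
    coords["O5'"] = place_atom(coords["C3'"], coords["C4'"], coords["C5'"],
                               1.44, 109.0, spec.gamma_target)
    coords["PA"] = place_atom(coords["C4'"], coords["C5'"], coords["O5'"],
                              1.60, 120.0, 180.0)
    coords["O1A"] = place_atom(coords["C5'"], coords["O5'"], coords["PA"], 1.48, 109.5, 60.0)
    coords["O2A"] = place_atom(coords["C5'"], coords["O5'"], coords["PA"], 1.48, 109.5, -60.0)
    coords["O3A"] = place_atom(coords["C5'"], coords["O5'"], coords["PA"], 1.61, 104.0, 180.0)
    coords["PB"] = place_atom(coords["O5'"], coords["PA"], coords["O3A"], 1.61, 130.0, 180.0)
    o3b_bond = 1.61 if spec.include_gamma_phosphate else 1.48
    coords["O1B"] = place_atom(coords["PA"], coords["O3A"], coords["PB"], 1.48, 109.5, 60.0)
    coords["O2B"] = place_atom(coords["PA"], coords["O3A"], coords["PB"], 1.48, 109.5, -60.0)
    coords["O3B"] = place_atom(coords["PA"], coords["O3A"], coords["PB"], o3b_bond, 109.5, 180.0)
    if spec.include_gamma_phosphate:
        coords["PG"] = place_atom(coords["O3A"], coords["PB"], coords["O3B"], 1.61, 130.0, 180.0)
        coords["O1G"] = place_atom(coords["PB"], coords["O3B"], coords["PG"], 1.48, 109.5, 60.0)
        coords["O2G"] = place_atom(coords["PB"], coords["O3B"], coords["PG"], 1.48, 109.5, -60.0)
        coords["O3G"] = place_atom(coords["PB"], coords["O3B"], coords["PG"], 1.48, 109.5, 180.0)

    # 3' phosphate chain: C3'-O3'-PC(-O1C,-O2C)-O3C-PD(-O1D,-O2D,-O3D)
    coords["PC"] = place_atom(coords["C4'"], coords["C3'"], coords["O3'"],
                              1.60, 120.0, -120.0)
    coords["O1C"] = place_atom(coords["C3'"], coords["O3'"], coords["PC"], 1.48, 109.5, 60.0)
    coords["O2C"] = place_atom(coords["C3'"], coords["O3'"], coords["PC"], 1.48, 109.5, -60.0)
    coords["O3C"] = place_atom(coords["C3'"], coords["O3'"], coords["PC"], 1.61, 104.0, 180.0)
    coords["PD"] = place_atom(coords["O3'"], coords["PC"], coords["O3C"], 1.61, 130.0, 180.0)
    coords["O1D"] = place_atom(coords["PC"], coords["O3C"], coords["PD"], 1.48, 109.5, 60.0)
    coords["O2D"] = place_atom(coords["PC"], coords["O3C"], coords["PD"], 1.48, 109.5, -60.0)
    coords["O3D"] = place_atom(coords["PC"], coords["O3C"], coords["PD"], 1.48, 109.5, 180.0)

    order = ["N9", "C8", "N7", "C5", "C4", "N3", "C2", "N2", "N1", "C6", "O6",
             "C1'", "C2'", "C3'", "C4'", "C5'", "O2'", "O3'", "O4'", "O5'",
             "PA", "O1A", "O2A", "O3A", "PB", "O1B", "O2B", "O3B"]
    if spec.include_gamma_phosphate:
        order += ["PG", "O1G", "O2G", "O3G"]
    order += ["PC", "O1C", "O2C", "O3C", "PD", "O1D", "O2D", "O3D"]

    atoms = [Atom(serial=serial_start + i, name=name, element=_element_of(name),
                  residue_name=spec.ligand_code, residue_seq=residue_seq,
                  chain_id=chain_id, coords=np.round(coords[name], 3), is_hetero=True)
             for i, name in enumerate(order)]
    ligand = LigandInstance(ligand_code=spec.ligand_code, atoms=atoms,
                            chain_id=chain_id, residue_seq=residue_seq)
    ligand.validate_geometry()
    measured_chi = compute_torsions(ligand).chi
    if abs((measured_chi - spec.chi_target + 180.0) % 360.0 - 180.0) > 0.5:
        raise RuntimeError(f"glycosidic placement drifted: chi {measured_chi:.2f} "
                           f"vs target {spec.chi_target:.2f}")
    header = [
        f"synthetic (p)ppGpp ligand {spec.ligand_code}",
        f"targets P={spec.P_target:.2f} nu_max={spec.nu_max_target:.2f} "
        f"chi={spec.chi_target:.2f} gamma={spec.gamma_target:.2f}",
        "ideal geometry: ring C-C 1.525-1.527, C-O 1.415-1.452, P-O ester 1.60-1.61,",
        "P-O terminal 1.48, purine rings planar fused polygons side 1.38",
    ]
    model = StructureModel(pdb_id="LIG0", model_index=0, atoms=atoms)
    return ligand, write_pdb(model, header_lines=header)


# ---------------------------------------------------------------------------
# planted binding sites


@dataclass(frozen=True)
class PlantedContact:
    """One contact to plant: category, target ligand atom, geometry."""

    category: str
    ligand_atom: str
    distance: float
    angle: float | None = None


def nine_category_contacts() -> tuple[PlantedContact, ...]:
    """Default planted-site recipe: one contact per interaction category,
    placed on well-separated ligand atoms with margins >= 0.1 Å inside each
    category's geometric window."""
    return (
        PlantedContact("hbond", "N2", 3.0, 160.0),
        PlantedContact("weak_hbond", "O2'", 2.5, 100.0),
        PlantedContact("polar", "N7", 3.4, 95.0),
        PlantedContact("weak_polar", "N1", 3.8),
        PlantedContact("ionic", "O1D", 3.7),
        PlantedContact("metal", "O1B", 2.1),
        PlantedContact("aromatic", "C5", 3.6),
        PlantedContact("vdw", "C8", 3.3),
        PlantedContact("vdw_clash", "O3D", 2.5),
    )


@dataclass
class SiteSpec:
    """Recipe for a synthetic binding site around a ligand."""

    contacts: tuple[PlantedContact, ...] = field(default_factory=nine_category_contacts)
    decoys: int = 4
    seed: int = 0

    @property
    def expected_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.contacts:
            counts[c.category] = counts.get(c.category, 0) + 1
        return counts


def _neighbors(ligand: LigandInstance, name: str) -> list[np.ndarray]:
    target = ligand.atom(name)
    out = []
    for a in ligand.atoms:
        if a.name == name:
            continue
        cut = 1.95 if "P" in (a.element, target.element) else 1.85
        if np.linalg.norm(a.coords - target.coords) <= cut:
            out.append(a.coords)
    return out


def _outward(ligand: LigandInstance, name: str) -> np.ndarray:
    target = ligand.atom(name)
    nbrs = _neighbors(ligand, name)
    u = target.coords - np.mean(nbrs, axis=0)
    norm = np.linalg.norm(u)
    if norm < 1e-6:
        raise RuntimeError(f"no outward direction at {name}")
    return u / norm


def _perp(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, ref)
    return v / np.linalg.norm(v)


def _angled_from(origin: np.ndarray, antecedent: np.ndarray, distance: float,
                 angle_deg: float, e2: np.ndarray | None = None) -> np.ndarray:
    """Point at ``distance`` from origin making ``angle_deg`` with antecedent->origin."""
    e1 = origin - antecedent
    e1 /= np.linalg.norm(e1)
    if e2 is None:
        e2 = _perp(e1)
    phi = math.radians(180.0 - angle_deg)
    return origin + distance * (math.cos(phi) * e1 + math.sin(phi) * e2)


def _clearance(lig: LigandInstance, target_name: str,
               placed: Sequence[tuple[np.ndarray, str, str, bool]]) -> float:
    """Worst margin (Å) of placed partner atoms against every stray-contact rule.

    ``placed`` holds (position, residue_name, atom_name, is_hb_partner); the
    margin of a pair is its distance minus the largest threshold any detector
    would apply to it (polar/ionic 4.0, metal 3.0, vdW radii sum + slack;
    hydrogen-bond partner atoms are exempt from the vdW rule, mirroring the
    detector hierarchy).  Positive margins mean no stray contact.
    """
    worst = math.inf
    for lig_atom in lig.atoms:
        if lig_atom.name == target_name:
            continue
        lf = flags_for(lig.ligand_code, lig_atom.name, lig_atom.element)
        for pos, resname, aname, is_hb in placed:
            ef = flags_for(resname, aname)
            elem = "MG" if resname == "MG" else aname[0]
            d = float(np.linalg.norm(lig_atom.coords - pos))
            polar_pair = (lf.donor and ef.acceptor) or (ef.donor and lf.acceptor)
            ionic_pair = (lf.anionic and ef.cationic) or (lf.cationic and ef.anionic)
            if ef.metal:
                req = 3.1 if lig_atom.element in ("N", "O") else 2.8
            elif polar_pair or ionic_pair:
                req = 4.1
            elif is_hb:
                req = (VDW_RADII[lig_atom.element.upper()] + VDW_RADII[elem]) - 0.35
            else:
                req = VDW_RADII[lig_atom.element.upper()] + VDW_RADII[elem] + 0.2
            worst = min(worst, d - req)
    return worst


def _candidate_directions(u0: np.ndarray) -> list[np.ndarray]:
    """Deterministic unit-vector fan biased around u0 (near-hemisphere cover)."""
    e2, e3 = _perp(u0), np.cross(u0, _perp(u0))
    out = [u0]
    for tilt in (0.4, 0.8, 1.4, 2.2, 4.0):
        for k in range(12):
            ang = 2.0 * math.pi * k / 12.0
            v = u0 + tilt * (math.cos(ang) * e2 + math.sin(ang) * e3)
            out.append(v / np.linalg.norm(v))
    return out


def _best_direction(lig: LigandInstance, name: str, builder_fn):
    """Deterministically pick the placement direction maximizing the margin.

    ``builder_fn(v)`` maps a unit direction to placed-atom tuples
    (position, residue_name, atom_name, is_hb_partner).  Candidates are the
    outward direction and tilted blends around it.
    """
    best, best_score = None, -math.inf
    for v in _candidate_directions(_outward(lig, name)):
        placed = builder_fn(v)
        score = _clearance(lig, name, placed)
        if score > best_score + 1e-9:
            best, best_score = placed, score
    return best


def _place_free(lig: LigandInstance, target_name: str, anchor: np.ndarray,
                away_from: np.ndarray, bond: float, resname: str, aname: str,
                is_hb: bool = False) -> np.ndarray:
    """Place a follow-up atom bonded to ``anchor`` with a free direction,
    preferring directions away from the ligand and maximizing the margin."""
    e1 = anchor - away_from
    e1 /= np.linalg.norm(e1)
    best, best_score = None, -math.inf
    for v in _candidate_directions(e1):
        pos = anchor + bond * v
        score = _clearance(lig, target_name, [(pos, resname, aname, is_hb)])
        if score > best_score + 1e-9:
            best, best_score = pos, score
    return best


class _SiteBuilder:
    def __init__(self, ligand: LigandInstance):
        self.ligand = ligand
        self.atoms: list[Atom] = []
        self.serial = max(a.serial for a in ligand.atoms) + 1
        self.resseq = 100
        self.planted_pairs: list[tuple[str, str, int]] = []  # (category, lig atom, env serial)
        self.hb_serials: set[int] = set()

    def add(self, name: str, element: str, resname: str, xyz: np.ndarray,
            chain: str = "B", resseq: int | None = None) -> Atom:
        atom = Atom(serial=self.serial, name=name, element=element,
                    residue_name=resname, residue_seq=resseq or self.resseq,
                    chain_id=chain, coords=np.round(xyz, 3), is_hetero=resname
                    in ("MG", "HOH"))
        self.atoms.append(atom)
        self.serial += 1
        return atom

    def new_residue(self) -> int:
        self.resseq += 1
        return self.resseq


def _plant(builder: _SiteBuilder, planted: PlantedContact) -> None:
    lig = builder.ligand
    cat, name = planted.category, planted.ligand_atom
    L = lig.atom(name).coords
    builder.new_residue()

    if cat in ("hbond", "weak_hbond"):
        nbrs = _neighbors(lig, name)
        if len(nbrs) != 1:
            raise RuntimeError(f"{cat} plant needs a single-antecedent donor, got {name}")
        # the donor angle fixes a cone about the antecedent axis; pick the
        # cone azimuth with the largest margin
        e1 = L - nbrs[0]
        e1 /= np.linalg.norm(e1)
        e2, e3 = _perp(e1), np.cross(e1, _perp(e1))
        best, best_score = None, -math.inf
        for k in range(24):
            ang = 2.0 * math.pi * k / 24.0
            ee = math.cos(ang) * e2 + math.sin(ang) * e3
            pos = _angled_from(L, nbrs[0], planted.distance, planted.angle, e2=ee)
            score = _clearance(lig, name, [(pos, "ASN", "OD1", True)])
            if score > best_score + 1e-9:
                best, best_score = pos, score
        pos = best
        partner = builder.add("OD1", "O", "ASN", pos)
        builder.add("CG", "C", "ASN",
                    _place_free(lig, name, pos, L, 1.23, "ASN", "CG"))
        builder.planted_pairs.append((cat, name, partner.serial))
        builder.hb_serials.add(partner.serial)
    elif cat == "polar":
        placed = _best_direction(
            lig, name, lambda v: [(L + planted.distance * v, "SER", "OG", False)])
        pos = placed[0][0]
        partner = builder.add("OG", "O", "SER", pos)
        # partner-side donor angle: rotate the CB azimuth for margin
        e1 = pos - L
        e1 /= np.linalg.norm(e1)
        e2, e3 = _perp(e1), np.cross(e1, _perp(e1))
        best_cb, best_score = None, -math.inf
        for k in range(24):
            ang = 2.0 * math.pi * k / 24.0
            ee = math.cos(ang) * e2 + math.sin(ang) * e3
            cb = _angled_from(pos, L, 1.53, planted.angle, e2=ee)
            score = _clearance(lig, name, [(cb, "SER", "CB", False)])
            if score > best_score + 1e-9:
                best_cb, best_score = cb, score
        builder.add("CB", "C", "SER", best_cb)
        builder.planted_pairs.append((cat, name, partner.serial))
    elif cat == "weak_polar":
        # acceptor partner against a ligand donor keeps the crowded phosphate
        # oxygens out of play
        placed = _best_direction(
            lig, name, lambda v: [(L + planted.distance * v, "GLN", "OE1", False)])
        pos = placed[0][0]
        partner = builder.add("OE1", "O", "GLN", pos)
        builder.add("CD", "C", "GLN", _place_free(lig, name, pos, L, 1.23, "GLN", "CD"))
        builder.planted_pairs.append((cat, name, partner.serial))
    elif cat == "ionic":
        placed = _best_direction(
            lig, name, lambda v: [(L + planted.distance * v, "ARG", "NH1", False)])
        pos = placed[0][0]
        partner = builder.add("NH1", "N", "ARG", pos)
        builder.add("CZ", "C", "ARG", _place_free(lig, name, pos, L, 1.33, "ARG", "CZ"))
        builder.planted_pairs.append((cat, name, partner.serial))
    elif cat == "metal":
        placed = _best_direction(
            lig, name, lambda v: [(L + planted.distance * v, "MG", "MG", False)])
        pos = placed[0][0]
        metal = builder.add("MG", "MG", "MG", pos, chain="M", resseq=201)
        builder.planted_pairs.append((cat, name, metal.serial))
        builder.new_residue()
        od1 = _place_free(lig, name, pos, L, 2.2, "ASP", "OD1")
        builder.add("OD1", "O", "ASP", od1)
        builder.add("CG", "C", "ASP", _place_free(lig, name, od1, pos, 1.25, "ASP", "CG"))
    elif cat == "aromatic":
        ring = lig.coords_of(GUANINE_6RING)
        centroid = ring.mean(axis=0)
        centred = ring - centroid
        normal = np.linalg.svd(centred)[2][-1]
        # keep the partner ring's centroid > 4.5 Å from the guanine 5-ring
        # centroid by sliding it away from the pentagon
        five = lig.coords_of(("C4", "N9", "C8", "N7", "C5"))
        slide = centroid - five.mean(axis=0)
        slide -= np.dot(slide, normal) * normal
        slide /= np.linalg.norm(slide)
        # stack on whichever face is clear of the ribose/phosphates
        others = np.array([a.coords for a in lig.atoms])
        scores = []
        for sgn in (1.0, -1.0):
            center = centroid + sgn * planted.distance * normal + 0.75 * slide
            scores.append((np.min(np.linalg.norm(others - center, axis=1)), sgn))
        sgn = max(scores)[1]
        center = centroid + sgn * planted.distance * normal + 0.75 * slide
        e1 = slide
        e2 = np.cross(normal, e1)
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        builder.new_residue()
        first_serial = builder.serial
        for k, ring_name in enumerate(names):
            theta = 2.0 * math.pi * k / 6.0
            pos = center + 1.38 * (math.cos(theta) * e1 + math.sin(theta) * e2)
            builder.add(ring_name, "C", "TYR", pos, resseq=builder.resseq)
        builder.planted_pairs.append((cat, "C5", first_serial))
    elif cat == "vdw":
        placed = _best_direction(
            lig, name, lambda v: [(L + planted.distance * v, "LEU", "CD1", False)])
        pos = placed[0][0]
        partner = builder.add("CD1", "C", "LEU", pos)
        builder.add("CG", "C", "LEU", _place_free(lig, name, pos, L, 1.53, "LEU", "CG"))
        builder.planted_pairs.append((cat, name, partner.serial))
    elif cat == "vdw_clash":
        placed = _best_direction(
            lig, name, lambda v: [(L + planted.distance * v, "ALA", "CB", False)])
        pos = placed[0][0]
        partner = builder.add("CB", "C", "ALA", pos)
        builder.add("CA", "C", "ALA", _place_free(lig, name, pos, L, 1.53, "ALA", "CA"))
        builder.planted_pairs.append((cat, name, partner.serial))
    else:
        raise ValueError(f"unknown planted category {cat!r}")


def _verify_site(builder: _SiteBuilder, criteria: InteractionCriteria,
                 margin: float = 0.05) -> None:
    """Geometric margin audit: no unplanned ligand-environment pair may fall
    inside any category window.  Raises on violation (unsatisfiable site)."""
    lig = builder.ligand
    planted = {(name, serial) for _, name, serial in builder.planted_pairs}
    planted_atoms = {serial for _, _, serial in builder.planted_pairs}
    for env in builder.atoms:
        eflags = flags_for(env.residue_name, env.name, env.element)
        for la in lig.atoms:
            lflags = flags_for(lig.ligand_code, la.name, la.element)
            d = float(np.linalg.norm(env.coords - la.coords))
            if (la.name, env.serial) in planted:
                continue
            if env.residue_name == "HOH":
                continue
            if eflags.metal:
                if la.element in ("N", "O") and d < criteria.metal_dist_max + margin:
                    raise RuntimeError(f"stray metal contact {la.name}-{env.name} {d:.2f}")
                continue
            polar_pair = (lflags.donor and eflags.acceptor) or (eflags.donor and lflags.acceptor)
            ionic_pair = (lflags.anionic and eflags.cationic) or (lflags.cationic and eflags.anionic)
            if (polar_pair or ionic_pair) and d < criteria.weak_polar_dist_max + margin:
                raise RuntimeError(f"stray polar/ionic pair {la.name}-{env.name} {d:.2f}")
            in_hb = env.serial in builder.hb_serials or any(
                cat in ("hbond", "weak_hbond") and n == la.name
                for cat, n, _ in builder.planted_pairs)
            if not polar_pair and not in_hb:
                rsum = VDW_RADII[la.element.upper()] + VDW_RADII[env.element.upper()]
                if d < rsum + criteria.vdw_slack + margin:
                    raise RuntimeError(f"stray vdw pair {la.name}-{env.name} {d:.2f}")


def build_site(ligand: LigandInstance, spec: SiteSpec,
               pdb_id: str = "SITE0",
               criteria: InteractionCriteria | None = None) -> StructureModel:
    """Assemble a complex: the ligand plus planted partner fragments and decoys.

    Every planted contact is recoverable by the matching detector; decoy
    atoms lie beyond the environment cutoff.  Deterministic for a fixed
    ``spec.seed``.
    """
    criteria = criteria or InteractionCriteria()
    builder = _SiteBuilder(ligand)
    for planted in spec.contacts:
        _plant(builder, planted)
    rng = np.random.default_rng(spec.seed)
    lig_xyz = np.array([a.coords for a in ligand.atoms])
    centroid = lig_xyz.mean(axis=0)
    resseq = 400
    placed = 0
    while placed < spec.decoys:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = centroid + (9.0 + 3.0 * rng.random()) * direction
        if np.min(np.linalg.norm(lig_xyz - pos, axis=1)) < criteria.environment_cutoff + 1.0:
            continue
        resseq += 1
        builder.add("CA", "C", "GLY", pos, chain="D", resseq=resseq)
        placed += 1
    _verify_site(builder, criteria)
    return StructureModel(pdb_id=pdb_id, model_index=0,
                          atoms=list(ligand.atoms) + builder.atoms)


def build_water_bridge_site(ligand: LigandInstance, ligand_atom: str = "O6",
                            n_bridges: int = 1, pdb_id: str = "WAT0") -> StructureModel:
    """Complex with planted water-mediated bridges L...HOH...ASN OD1.

    Both legs are 2.9 Å; the bridge is bent (100 degrees at the water) so the
    protein-side partner stays inside the 5 Å ligand environment.
    """
    builder = _SiteBuilder(ligand)
    L = ligand.atom(ligand_atom).coords
    u = _outward(ligand, ligand_atom)
    for k in range(n_bridges):
        e2 = _perp(u) if k % 2 == 0 else -_perp(u)
        # fan successive bridges out so the waters are well separated
        tilt = math.radians(35.0) * k
        direction = math.cos(tilt) * u + math.sin(tilt) * e2
        w = L + 2.9 * direction
        water = builder.add("O", "O", "HOH", w, chain="W", resseq=301 + k)
        # bend 100 degrees at the water so the protein leg stays inside the
        # 5 Å ligand environment
        e_bend = e2 - np.dot(e2, direction) * direction
        e_bend /= np.linalg.norm(e_bend)
        phi = math.radians(180.0 - 100.0)
        prot = w + 2.9 * (math.cos(phi) * direction + math.sin(phi) * e_bend)
        builder.new_residue()
        builder.add("OD1", "O", "ASN", prot)
        away = prot + 1.23 * (prot - w) / np.linalg.norm(prot - w)
        builder.add("CG", "C", "ASN", away)
    return StructureModel(pdb_id=pdb_id, model_index=0,
                          atoms=list(ligand.atoms) + builder.atoms)


# ---------------------------------------------------------------------------
# glycosidic torsion ensembles


@dataclass(frozen=True)
class EnsembleSpec:
    """Von Mises mixture over glycosidic angles: syn and anti modes.

    Defaults emulate an enhanced-sampling free-nucleotide run that occupies
    the syn well most of the time with a minor anti population.
    """

    n_frames: int = 10000
    syn_fraction: float = 0.7
    kappa: float = 12.0
    syn_center: float = 45.0
    anti_center: float = -135.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.syn_fraction <= 1.0:
            raise ValueError("syn_fraction must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")


def sample_chi_ensemble(spec: EnsembleSpec) -> np.ndarray:
    """Draw a chi series (degrees in (-180, 180]) from the syn/anti mixture."""
    rng = np.random.default_rng(spec.seed)
    pick_syn = rng.random(spec.n_frames) < spec.syn_fraction
    centers = np.where(pick_syn, math.radians(spec.syn_center),
                       math.radians(spec.anti_center))
    draws = rng.vonmises(centers, spec.kappa)
    deg = np.degrees(draws)
    deg[deg <= -180.0] += 360.0
    return deg


# ---------------------------------------------------------------------------
# annotated corpus

#: per-class site recipes mirroring the published class signatures:
#: synthetases and nucleotide-metabolic enzymes show tyrosine stacking,
#: arginine salt bridges and magnesium; GTPases show neither stacking nor
#: metals and bind mainly through hydrogen bonds / vdW; RNA polymerase
#: engages the phosphate chains with basic residues and magnesium.
CLASS_RECIPES: dict[str, tuple[PlantedContact, ...]] = {
    "synthetase": (
        PlantedContact("hbond", "N2", 3.0, 160.0),
        PlantedContact("aromatic", "C5", 3.6),
        PlantedContact("ionic", "O1D", 3.7),
        PlantedContact("metal", "O1B", 2.1),
        PlantedContact("vdw", "C8", 3.3),
    ),
    "nucleotide_metabolic": (
        PlantedContact("hbond", "N2", 3.0, 160.0),
        PlantedContact("hbond", "O2'", 3.0, 150.0),
        PlantedContact("aromatic", "C5", 3.6),
        PlantedContact("ionic", "O1D", 3.7),
        PlantedContact("metal", "O1B", 2.1),
    ),
    "gtpase": (
        PlantedContact("hbond", "N2", 3.0, 160.0),
        PlantedContact("polar", "N7", 3.4, 95.0),
        PlantedContact("vdw", "C8", 3.3),
        PlantedContact("weak_polar", "N1", 3.8),
    ),
    "rna_polymerase": (
        PlantedContact("hbond", "N2", 3.0, 160.0),
        PlantedContact("ionic", "O1D", 3.7),
        PlantedContact("metal", "O1B", 2.1),
        PlantedContact("vdw", "C8", 3.3),
        PlantedContact("weak_hbond", "O2'", 2.5, 100.0),
    ),
}

#: per-class ligand conformations (P, nu_max, chi, gamma), patterned on the
#: spread of receptor-bound conformers: C3'-endo in synthetases, C2'-endo
#: elsewhere, syn glycosidic in the nucleotide-metabolic class
_CLASS_CONFORMERS = {
    "synthetase": (31.47, 36.96, 171.65, 61.18),
    "nucleotide_metabolic": (151.01, 44.27, 65.89, -143.14),
    "gtpase": (158.59, 34.92, -112.79, 53.43),
    "rna_polymerase": (170.36, 28.23, -116.08, -177.02),
}


@dataclass
class SyntheticComplex:
    annotation: ComplexAnnotation
    model: StructureModel
    ligand: LigandInstance
    expected_counts: dict[str, int]


def build_corpus(n_per_class: int = 2, seed: int = 0,
                 classes: Sequence[str] = tuple(CLASS_RECIPES)) -> list[SyntheticComplex]:
    """Annotated fixture corpus: ``n_per_class`` complexes per protein class.

    Ligand conformations are jittered a few degrees around the class
    conformer; the planted interaction pattern follows the class recipe.
    Deterministic for a fixed seed.
    """
    seeds = np.random.SeedSequence(seed).spawn(len(classes) * n_per_class)
    out = []
    idx = 0
    for cls in classes:
        P0, numax0, chi0, gamma0 = _CLASS_CONFORMERS[cls]
        for rep in range(n_per_class):
            child = seeds[idx]
            idx += 1
            rng = np.random.default_rng(child)
            sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            spec = LigandSpec(
                P_target=P0 + rng.uniform(-4.0, 4.0),
                nu_max_target=float(np.clip(numax0 + rng.uniform(-2.0, 2.0), 6.0, 59.0)),
                chi_target=chi0 + rng.uniform(-4.0, 4.0),
                gamma_target=gamma0 + rng.uniform(-4.0, 4.0),
                include_gamma_phosphate=(cls == "synthetase" and rep % 2 == 1))
            ligand, _ = build_nucleotide(spec, seed=sub_seed)
            pdb_id = f"{cls[:3].upper()}{rep}"
            site_spec = SiteSpec(contacts=CLASS_RECIPES[cls], seed=sub_seed)
            model = build_site(ligand, site_spec, pdb_id=pdb_id)
            ann = ComplexAnnotation(pdb_id=pdb_id, ligand_code=spec.ligand_code,
                                    functional_class=cls, source="fixture")
            out.append(SyntheticComplex(annotation=ann, model=model, ligand=ligand,
                                        expected_counts=site_spec.expected_counts))
    return out


def write_corpus(complexes: Sequence[SyntheticComplex], outdir, seed: int | None = None) -> Path:
    """Write corpus PDBs plus a manifest TSV (id, class, planted-truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["fixture_id\tfunctional_class\tligand_code\tplanted_truth"]
    for cpx in complexes:
        header = [f"synthetic complex {cpx.annotation.pdb_id} "
                  f"class {cpx.annotation.functional_class}"]
        if seed is not None:
            header.append(f"seed {seed}")
        write_pdb(cpx.model, outdir / f"{cpx.annotation.pdb_id}.pdb", header_lines=header)
        lines.append(f"{cpx.annotation.pdb_id}\t{cpx.annotation.functional_class}\t"
                     f"{cpx.annotation.ligand_code}\t{json.dumps(cpx.expected_counts)}")
    manifest = outdir / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    class_map = ["pdb_id\tfunctional_class"] + [
        f"{c.annotation.pdb_id}\t{c.annotation.functional_class}" for c in complexes]
    (outdir / "class_map.tsv").write_text("\n".join(class_map) + "\n")
    return manifest
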