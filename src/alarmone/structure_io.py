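"""PDB-format structure handling for alarmone nucleotide complexes.

Parsing is backed by :mod:`gemmi`; the records are flattened into plain
:class:`Atom` lists with a single alternate-location policy (keep the highest
occupancy, ties broken in favour of altloc ``A``).  Writing uses the standard
fixed-column PDB layout so that synthetic fixtures are byte-deterministic.

The module also extracts (p)ppGpp ligands (PDB chemical component codes
``G4P`` for ppGpp, ``C1Z``/``0O2`` for pppGpp) with canonical atom naming,
selects the protein environment around a ligand, and assigns physicochemical
atom types from a bundled residue-template table.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "StructureModel",
    "LigandInstance",
    "AtomFlags",
    "AtomTyping",
    "PDBParseError",
    "parse_pdb",
    "write_pdb",
    "extract_ligands",
    "select_environment",
    "assign_atom_types",
    "count_hbond_capable_atoms",
    "is_water",
    "is_metal",
    "LIGAND_CODES",
    "GUANINE_ATOMS",
    "RIBOSE_ATOMS",
    "PHOSPHATE_5PRIME_ATOMS",
    "PHOSPHATE_3PRIME_ATOMS",
    "GAMMA_PHOSPHATE_ATOMS",
]

METAL_ELEMENTS = {"MG", "MN", "ZN", "NA", "K", "CA"}

#: canonical ligand atom groups (PDB chemical-component naming, primes not stars)
GUANINE_ATOMS = ("N1", "C2", "N2", "N3", "C4", "C5", "C6", "O6", "N7", "C8", "N9")
GUANINE_RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
GUANINE_6RING = ("C4", "C5", "C6", "N1", "C2", "N3")
GUANINE_5RING = ("C4", "N9", "C8", "N7", "C5")
RIBOSE_ATOMS = ("C1'", "C2'", "C3'", "C4'", "C5'", "O2'", "O3'", "O4'", "O5'")
RIBOSE_RING_ATOMS = ("O4'", "C1'", "C2'", "C3'", "C4'")
PHOSPHATE_5PRIME_ATOMS = ("PA", "O1A", "O2A", "O3A", "PB", "O1B", "O2B", "O3B")
GAMMA_PHOSPHATE_ATOMS = ("PG", "O1G", "O2G", "O3G")
PHOSPHATE_3PRIME_ATOMS = ("PC", "O1C", "O2C", "O3C", "PD", "O1D", "O2D", "O3D")

LIGAND_CODES = {"G4P", "C1Z", "0O2"}
#: codes whose chemistry includes a 5' gamma-phosphate (pppGpp)
TRIPHOSPHATE_CODES = {"C1Z", "0O2"}


class PDBParseError(ValueError):
    """Raised when a PDB text cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    """One atom record (coordinates in Å, PDB conventions)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False
    formal_charge: int = 0
    altloc: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial} {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name}: element must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.serial} {self.name}: occupancy outside [0, 1]")


def is_water(atom: Atom) -> bool:
    return atom.residue_name == "HOH"


def is_metal(atom: Atom) -> bool:
    return atom.element.upper() in METAL_ELEMENTS and atom.residue_name != "HOH"


@dataclass
class StructureModel:
    """One coordinate model: an ordered atom list plus water/metal flags."""

    pdb_id: str
    model_index: int
    atoms: list[Atom]

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError(f"model {self.model_index}: duplicate atom serials")

    @property
    def waters(self) -> np.ndarray:
        return np.array([is_water(a) for a in self.atoms], dtype=bool)

    @property
    def metals(self) -> np.ndarray:
        return np.array([is_metal(a) for a in self.atoms], dtype=bool)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def atom_by_serial(self, serial: int) -> Atom:
        for a in self.atoms:
            if a.serial == serial:
                return a
        raise KeyError(serial)


@dataclass
class LigandInstance:
    """One extracted nucleotide ligand with canonically named atoms.

    ``completeness`` maps atom-group name (guanine, ribose, phosphate_5prime,
    phosphate_3prime, gamma_phosphate) to whether every atom of the group is
    present.  Incomplete ligands are legitimate (low-resolution entries) and
    are returned flagged rather than dropped.
    """

    ligand_code: str
    atoms: list[Atom]
    chain_id: str = "A"
    residue_seq: int = 1
    completeness: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.completeness:
            self.completeness = self._compute_completeness()

    def _compute_completeness(self) -> dict[str, bool]:
        names = {a.name for a in self.atoms}
        comp = {
            "guanine": set(GUANINE_ATOMS) <= names,
            "ribose": set(RIBOSE_ATOMS) <= names,
            "phosphate_5prime": set(PHOSPHATE_5PRIME_ATOMS) <= names,
            "phosphate_3prime": set(PHOSPHATE_3PRIME_ATOMS) <= names,
        }
        comp["gamma_phosphate"] = set(GAMMA_PHOSPHATE_ATOMS) <= names
        return comp

    @property
    def is_complete(self) -> bool:
        required = ["guanine", "ribose", "phosphate_5prime", "phosphate_3prime"]
        if self.ligand_code in TRIPHOSPHATE_CODES:
            required.append("gamma_phosphate")
        return all(self.completeness.get(k, False) for k in required)

    @property
    def has_gamma_phosphate(self) -> bool:
        return self.completeness.get("gamma_phosphate", False)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"ligand {self.ligand_code} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords_of(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.atom(n).coords for n in names], dtype=float)

    @property
    def serials(self) -> frozenset[int]:
        return frozenset(a.serial for a in self.atoms)

    def validate_geometry(self, plane_rms_max: float = 0.2,
                          ring_bond_range: tuple[float, float] = (1.3, 1.7)) -> None:
        """Check guanine planarity and ribose ring closure; raise ValueError on failure."""
        names = {a.name for a in self.atoms}
        if set(GUANINE_RING_ATOMS) <= names:
            pts = self.coords_of(GUANINE_RING_ATOMS)
            centred = pts - pts.mean(axis=0)
            # RMS distance from the best-fit plane = smallest singular direction
            rms = np.sqrt(np.mean(np.linalg.svd(centred)[2][-1].dot(centred.T) ** 2))
            if rms > plane_rms_max:
                raise ValueError(f"guanine ring deviates {rms:.3f} Å RMS from planarity")
        if set(RIBOSE_RING_ATOMS) <= names:
            pts = self.coords_of(RIBOSE_RING_ATOMS)
            lo, hi = ring_bond_range
            for i in range(5):
                d = float(np.linalg.norm(pts[(i + 1) % 5] - pts[i]))
                if not lo <= d <= hi:
                    raise ValueError(
                        f"ribose ring bond {RIBOSE_RING_ATOMS[i]}-{RIBOSE_RING_ATOMS[(i + 1) % 5]}"
                        f" = {d:.2f} Å outside [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# parsing / writing


def _coerce_text(source) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        if "\n" not in source and os.path.exists(source):
            return Path(source).read_text()
        return source
    if hasattr(source, "read"):
        return source.read()
    raise TypeError(f"cannot read PDB from {type(source)!r}")


def _validate_records(text: str) -> None:
    seen_atom = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            seen_atom = True
            if len(line) < 54:
                raise PDBParseError(f"line {lineno}: truncated coordinate record")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: malformed {what} coordinate field {line[lo:hi]!r}"
                    ) from None
    if not seen_atom:
        raise PDBParseError("no ATOM/HETATM records found (empty or non-PDB input)")


def _canonical_atom_name(name: str) -> str:
    # old-style PDB primes use '*' (e.g. O2*)
    return name.replace("*", "'").strip()


def parse_pdb(source, pdb_id: str | None = None) -> list[StructureModel]:
    """Parse PDB text into a list of :class:`StructureModel`, one per MODEL record.

    ``source`` may be a path, PDB text, or a text stream.  Alternate locations
    are collapsed per (chain, residue, atom name): highest occupancy wins,
    ties go to altloc ``A``.
    """
    text = _coerce_text(source)
    _validate_records(text)
    try:
        structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise PDBParseError(str(exc)) from exc
    structure.setup_entities()
    name = pdb_id or (structure.name.strip() if structure.name.strip() else "XXXX")

    models: list[StructureModel] = []
    for model_index, model in enumerate(structure):
        best: dict[tuple, Atom] = {}
        order: list[tuple] = []
        for chain in model:
            for residue in chain:
                het = residue.het_flag == "H"
                for at in residue:
                    atom = Atom(
                        serial=at.serial,
                        name=_canonical_atom_name(at.name),
                        element=at.element.name.upper(),
                        residue_name=residue.name.strip().upper(),
                        residue_seq=residue.seqid.num,
                        chain_id=chain.name or " ",
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        is_hetero=het,
                        altloc=at.altloc if at.altloc != "\x00" else "",
                    )
                    key = (chain.name, residue.seqid.num, residue.name, atom.name)
                    if key not in best:
                        best[key] = atom
                        order.append(key)
                    else:
                        incumbent = best[key]
                        if (atom.occupancy, -ord(atom.altloc or "~")) > (
                                incumbent.occupancy, -ord(incumbent.altloc or "~")):
                            best[key] = atom
        models.append(StructureModel(pdb_id=name, model_index=model_index,
                                     atoms=[best[k] for k in order]))
    if not models:
        raise PDBParseError("no models found")
    return models


def _format_atom_line(a: Atom) -> str:
    record = "HETATM" if a.is_hetero else "ATOM  "
    name = a.name
    if len(name) < 4 and len(a.element) < 2:
        name = " " + name
    x, y, z = a.coords
    return (f"{record}{a.serial:5d} {name:<4s}{a.altloc or ' ':1s}{a.residue_name:<3s} "
            f"{a.chain_id:1s}{a.residue_seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}")


def write_pdb(models: StructureModel | Sequence[StructureModel],
              path: str | Path | None = None,
              header_lines: Sequence[str] = ()) -> str:
    """Serialize models to PDB text (fixed columns, 3-decimal coordinates)."""
    if isinstance(models, StructureModel):
        models = [models]
    out = io.StringIO()
    for line in header_lines:
        out.write(f"REMARK 250 {line}\n")
    multi = len(models) > 1
    for m in models:
        if multi:
            out.write(f"MODEL {m.model_index + 1:8d}\n")
        for a in m.atoms:
            out.write(_format_atom_line(a) + "\n")
        if multi:
            out.write("ENDMDL\n")
    out.write("END\n")
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# ligand extraction and environment selection


def normalize_ligand_code(code: str) -> str:
    code = code.strip().upper()
    return code


def extract_ligands(model: StructureModel,
                    codes: Iterable[str] = LIGAND_CODES) -> list[LigandInstance]:
    """Extract one :class:`LigandInstance` per matching hetero residue.

    Ligand codes are matched case-insensitively (the pppGpp code is printed
    both as ``0o2`` and ``0O2`` in the literature).  Residues with missing
    atoms are returned flagged incomplete rather than dropped.
    """
    wanted = {normalize_ligand_code(c) for c in codes}
    grouped: dict[tuple, list[Atom]] = {}
    for atom in model.atoms:
        if atom.residue_name in wanted:
            grouped.setdefault((atom.chain_id, atom.residue_seq, atom.residue_name), []).append(atom)
    ligands = []
    for (chain, seq, resname), atoms in sorted(grouped.items()):
        ligands.append(LigandInstance(ligand_code=resname, atoms=list(atoms),
                                      chain_id=chain, residue_seq=seq))
    return ligands


def select_environment(model: StructureModel, ligand: LigandInstance,
                       cutoff: float = 5.0) -> list[Atom]:
    """All non-ligand atoms whose minimum distance to any ligand atom is <= cutoff (Å)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_serials = ligand.serials
    others = [a for a in model.atoms if a.serial not in lig_serials]
    if not others:
        return []
    lig_xyz = np.array([a.coords for a in ligand.atoms])
    other_xyz = np.array([a.coords for a in others])
    d2 = ((other_xyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(axis=2)
    keep = np.sqrt(d2.min(axis=1)) <= cutoff
    return [a for a, k in zip(others, keep) if k]


# ---------------------------------------------------------------------------
# atom typing


FLAG_NAMES = ("donor", "acceptor", "aromatic", "cationic", "anionic", "metal", "hydrophobic")


@dataclass(frozen=True)
class AtomFlags:
    donor: bool = False
    acceptor: bool = False
    aromatic: bool = False
    cationic: bool = False
    anionic: bool = False
    metal: bool = False
    hydrophobic: bool = False

    @property
    def hbond_capable(self) -> bool:
        return self.donor or self.acceptor


_NULL_FLAGS = AtomFlags()

#: ligand codes sharing the ppGpp/pppGpp templates
_TEMPLATE_ALIASES = {"0O2": "C1Z"}


def _load_template_table() -> dict[tuple[str, str], AtomFlags]:
    table: dict[tuple[str, str], AtomFlags] = {}
    text = resources.files("alarmone.data").joinpath("residue_templates.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("residue\t"):
            continue
        residue, atom, flags = line.split("\t")
        tokens = () if flags.strip() == "-" else tuple(t.strip() for t in flags.split(","))
        unknown = set(tokens) - set(FLAG_NAMES)
        if unknown:
            raise ValueError(f"residue template {residue}/{atom}: unknown flags {unknown}")
        table[(residue, atom)] = AtomFlags(**{t: True for t in tokens})
    return table


_TEMPLATES: dict[tuple[str, str], AtomFlags] | None = None


def residue_templates() -> dict[tuple[str, str], AtomFlags]:
    global _TEMPLATES
    if _TEMPLATES is None:
        _TEMPLATES = _load_template_table()
    return _TEMPLATES


def flags_for(residue_name: str, atom_name: str, element: str = "") -> AtomFlags:
    """Deterministic typing for one atom: template lookup, then element heuristic."""
    templates = residue_templates()
    residue = _TEMPLATE_ALIASES.get(residue_name, residue_name)
    hit = templates.get((residue, atom_name))
    if hit is not None:
        return hit
    hit = templates.get(("*", atom_name))
    if hit is not None:
        return hit
    element = (element or atom_name[:1]).upper()
    if element in METAL_ELEMENTS and residue_name not in ("HOH",) and atom_name == element:
        return AtomFlags(metal=True)
    if element in ("N", "O"):
        return AtomFlags(donor=True, acceptor=True)
    if element == "S":
        return AtomFlags(acceptor=True)
    if element == "C":
        return AtomFlags(hydrophobic=True)
    return _NULL_FLAGS


class AtomTyping:
    """Per-atom physicochemical flags for a model, keyed by atom serial."""

    def __init__(self, flags_by_serial: Mapping[int, AtomFlags]):
        self._flags = dict(flags_by_serial)

    def __getitem__(self, serial: int) -> AtomFlags:
        return self._flags.get(serial, _NULL_FLAGS)

    def flags(self, atom: Atom) -> AtomFlags:
        return self[atom.serial]

    def __len__(self) -> int:
        return len(self._flags)


def assign_atom_types(model: StructureModel) -> AtomTyping:
    """Assign donor/acceptor/aromatic/charge/metal flags to every atom of a model.

    Typing is a pure function of (residue name, atom name, element).  Unknown
    residues fall back to an element heuristic (N/O -> donor+acceptor) with a
    logged warning.
    """
    templates = residue_templates()
    standard_aa = {"ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
                   "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
                   "TYR", "VAL"}
    known_residues = ({r for r, _ in templates} | {"*"} | set(_TEMPLATE_ALIASES)
                      | standard_aa)
    warned: set[str] = set()
    out: dict[int, AtomFlags] = {}
    for atom in model.atoms:
        if atom.residue_name not in known_residues and atom.residue_name not in warned:
            logger.warning("unknown residue %s: typing by element heuristic", atom.residue_name)
            warned.add(atom.residue_name)
        out[atom.serial] = flags_for(atom.residue_name, atom.name, atom.element)
    return AtomTyping(out)


def ligand_atom_flags(ligand: LigandInstance) -> dict[str, AtomFlags]:
    """Typing for a bare ligand, keyed by canonical atom name."""
    code = ligand.ligand_code if ligand.ligand_code in LIGAND_CODES else (
        "C1Z" if ligand.has_gamma_phosphate else "G4P")
    return {a.name: flags_for(code, a.name, a.element) for a in ligand.atoms}


def count_hbond_capable_atoms(ligand: LigandInstance,
                              require_complete: bool = True) -> tuple[int, int]:
    """Count nitrogen and oxygen atoms able to donate or accept hydrogen bonds.

    With ``require_complete`` (default) an incomplete ligand raises, listing
    the missing atom groups; pass False to census a fragment (e.g. the free
    guanine base).
    """
    if require_complete and not ligand.is_complete:
        missing = [g for g, ok in ligand.completeness.items() if not ok]
        raise ValueError(f"ligand {ligand.ligand_code} incomplete; missing groups: {missing}")
    flags = ligand_atom_flags(ligand)
    n_n = sum(1 for a in ligand.atoms if a.element == "N" and flags[a.name].hbond_capable)
    n_o = sum(1 for a in ligand.atoms if a.element == "O" and flags[a.name].hbond_capable)
    return n_n, n_o
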