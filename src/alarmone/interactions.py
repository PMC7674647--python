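"""Geometric non-covalent interaction fingerprinting of ligand-protein complexes.

Nine contact categories are typed inside a 5 Å environment of the ligand:
van der Waals clash, van der Waals, hydrogen bond, weak hydrogen bond, ionic,
metal complex, aromatic (ring stacking), polar and weak polar.  Hydrogen
bonds follow the geometric window 2.8-3.5 Å with a donor angle of 120-180
degrees; weak hydrogen bonds are shorter than 2.8 Å with an angle below 120
degrees.  Crystal structures usually lack hydrogens, so the donor angle is
measured at the donor against its heavy-atom antecedent (proxy); explicit
hydrogens are used when present.

Double counting is resolved hierarchically so that the per-category counts
partition the contact list: metal > ionic > hbond > weak_hbond > polar >
weak_polar, with van der Waals contacts computed between atoms not engaged
in hydrogen bonding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import yaml

from .structure_io import (
    Atom,
    AtomFlags,
    AtomTyping,
    GUANINE_5RING,
    GUANINE_6RING,
    LigandInstance,
    StructureModel,
    assign_atom_types,
    is_metal,
    is_water,
    ligand_atom_flags,
    select_environment,
)

__all__ = [
    "CATEGORIES",
    "InteractionCriteria",
    "Partner",
    "Contact",
    "Fingerprint",
    "detect_hbonds",
    "detect_vdw",
    "detect_ionic",
    "detect_metal",
    "detect_aromatic",
    "detect_polar",
    "water_mediated_hbonds",
    "fingerprint_complex",
    "write_contacts_tsv",
    "donor_angle_proxy",
]

CATEGORIES = ("vdw_clash", "vdw", "hbond", "weak_hbond", "ionic",
              "metal", "aromatic", "polar", "weak_polar")

#: protein aromatic ring definitions (residue -> tuple of ring atom tuples)
PROTEIN_RINGS = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
}


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric thresholds for contact typing (distances in Å, angles in degrees)."""

    hbond_dist: tuple[float, float] = (2.8, 3.5)
    hbond_angle: tuple[float, float] = (120.0, 180.0)
    weak_hbond_dist_max: float = 2.8
    weak_hbond_angle_max: float = 120.0
    vdw_slack: float = 0.1
    clash_overlap: float = 0.4
    ionic_dist_max: float = 4.0
    metal_dist_max: float = 3.0
    aromatic_centroid_max: float = 4.5
    polar_dist_max: float = 3.5
    weak_polar_dist_max: float = 4.0
    environment_cutoff: float = 5.0

    def __post_init__(self) -> None:
        for name in ("weak_hbond_dist_max", "vdw_slack", "clash_overlap", "ionic_dist_max",
                     "metal_dist_max", "aromatic_centroid_max", "polar_dist_max",
                     "weak_polar_dist_max", "environment_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"criteria.{name} must be positive")
        for lo, hi in (self.hbond_angle,):
            if not (0 <= lo <= hi <= 180):
                raise ValueError("hbond_angle bounds must lie within [0, 180]")

    @classmethod
    def from_dict(cls, mapping: dict) -> "InteractionCriteria":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown criteria key(s): {sorted(unknown)}")
        coerced = {k: tuple(v) if isinstance(v, (list, tuple)) else v
                   for k, v in mapping.items()}
        return cls(**coerced)

    @classmethod
    def from_yaml(cls, path) -> "InteractionCriteria":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {f.name: list(v) if isinstance(v := getattr(self, f.name), tuple) else v
                for f in fields(self)}


class Partner(NamedTuple):
    chain: str
    residue_seq: int
    residue_name: str
    atom: str


@dataclass(frozen=True)
class Contact:
    """One typed ligand-protein interaction."""

    ligand_atom: str
    partner: Partner
    category: str
    distance: float
    angle: float | None = None
    water_mediated: bool = False
    subtype: str | None = None
    via: Partner | None = None
    bridge_partners: tuple[Partner, ...] = ()


def _partner(atom: Atom) -> Partner:
    return Partner(atom.chain_id, atom.residue_seq, atom.residue_name, atom.name)


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def donor_angle_proxy(donor: np.ndarray, antecedents: Sequence[np.ndarray],
                      acceptor: np.ndarray) -> float | None:
    """Hydrogen-free donor angle: max over heavy antecedents X of angle X-D...A.

    Returns None when the donor has no antecedent (e.g. water oxygen or an
    isolated probe), in which case distance-only classification applies.
    """
    angles = [_angle_deg(np.asarray(x, float), np.asarray(donor, float),
                         np.asarray(acceptor, float)) for x in antecedents]
    return max(angles) if angles else None


def _covalent_neighbors(atom: Atom, pool: Sequence[Atom],
                        element: str | None = None) -> list[Atom]:
    """Atoms of the same residue within covalent range (optionally by element)."""
    out = []
    for other in pool:
        if other.serial == atom.serial:
            continue
        if (other.chain_id, other.residue_seq, other.residue_name) != (
                atom.chain_id, atom.residue_seq, atom.residue_name):
            continue
        if element is not None and other.element.upper() != element:
            continue
        cut = 1.95 if "P" in (atom.element, other.element) or "S" in (
            atom.element, other.element) else 1.85
        if element == "H":
            cut = 1.3
        d = float(np.linalg.norm(other.coords - atom.coords))
        if 0.4 < d <= cut:
            out.append(other)
    return out


def _donor_angle(donor: Atom, acceptor: Atom, pool: Sequence[Atom]) -> float | None:
    """D-H...A angle when hydrogens are present, else the antecedent proxy."""
    hydrogens = _covalent_neighbors(donor, pool, element="H")
    if hydrogens:
        return max(_angle_deg(donor.coords, h.coords, acceptor.coords) for h in hydrogens)
    heavies = [a for a in _covalent_neighbors(donor, pool) if a.element.upper() != "H"]
    return donor_angle_proxy(donor.coords, [a.coords for a in heavies], acceptor.coords)


class _Pairing:
    """Shared lookup state for the pairwise detectors."""

    def __init__(self, ligand: LigandInstance, environment: Sequence[Atom],
                 typing: AtomTyping | None, model: StructureModel | None):
        self.ligand = ligand
        self.environment = list(environment)
        self.typing = typing
        self.lig_flags = ligand_atom_flags(ligand)
        self.pool: list[Atom] = (list(model.atoms) if model is not None
                                 else list(ligand.atoms) + self.environment)

    def flags(self, atom: Atom, on_ligand: bool) -> AtomFlags:
        if on_ligand:
            return self.lig_flags[atom.name]
        if self.typing is not None:
            return self.typing.flags(atom)
        from .structure_io import flags_for
        return flags_for(atom.residue_name, atom.name, atom.element)


def _classify_hbond(ctx: _Pairing, lig_atom: Atom, env_atom: Atom,
                    criteria: InteractionCriteria) -> tuple[str, float | None] | None:
    """Return (category, angle) for the hbond family, or None."""
    lf, ef = ctx.flags(lig_atom, True), ctx.flags(env_atom, False)
    directions = []
    if lf.donor and ef.acceptor:
        directions.append((lig_atom, env_atom))
    if ef.donor and lf.acceptor:
        directions.append((env_atom, lig_atom))
    if not directions:
        return None
    d = float(np.linalg.norm(lig_atom.coords - env_atom.coords))
    if d > criteria.hbond_dist[1]:
        return None
    angles = [_donor_angle(donor, acceptor, ctx.pool) for donor, acceptor in directions]
    known = [a for a in angles if a is not None]
    best = max(known) if known else None
    lo, hi = criteria.hbond_dist
    alo, ahi = criteria.hbond_angle
    if lo <= d <= hi and (best is None or alo <= best <= ahi):
        return "hbond", best
    if d < criteria.weak_hbond_dist_max and (best is None or best < criteria.weak_hbond_angle_max):
        return "weak_hbond", best
    return None


def detect_hbonds(ligand: LigandInstance, environment: Sequence[Atom],
                  typing: AtomTyping | None = None,
                  criteria: InteractionCriteria | None = None,
                  model: StructureModel | None = None,
                  include_waters: bool = False,
                  exclude_pairs: set | None = None) -> list[Contact]:
    """Hydrogen bonds and weak hydrogen bonds between ligand and environment.

    A donor-acceptor pair at 2.8-3.5 Å with donor angle 120-180 degrees is an
    hbond; a pair below 2.8 Å with angle below 120 degrees is a weak_hbond
    (both conditions, following the stated geometric definition).  Pairs with
    no resolvable donor angle are classified on distance alone.
    """
    criteria = criteria or InteractionCriteria()
    ctx = _Pairing(ligand, environment, typing, model)
    exclude_pairs = exclude_pairs or set()
    contacts = []
    for env_atom in ctx.environment:
        if is_metal(env_atom) or (not include_waters and is_water(env_atom)):
            continue
        for lig_atom in ligand.atoms:
            if (lig_atom.serial, env_atom.serial) in exclude_pairs:
                continue
            hit = _classify_hbond(ctx, lig_atom, env_atom, criteria)
            if hit is not None:
                category, angle = hit
                contacts.append(Contact(
                    ligand_atom=lig_atom.name, partner=_partner(env_atom),
                    category=category,
                    distance=float(np.linalg.norm(lig_atom.coords - env_atom.coords)),
                    angle=angle))
    return _sorted(contacts)


def detect_polar(ligand: LigandInstance, environment: Sequence[Atom],
                 typing: AtomTyping | None = None,
                 criteria: InteractionCriteria | None = None,
                 model: StructureModel | None = None,
                 exclude_pairs: set | None = None) -> list[Contact]:
    """Angle-free donor/acceptor proximity: polar (<= 3.5 Å) and weak polar (<= 4.0 Å).

    Pairs already classified as hbond or weak_hbond are excluded, so the four
    hydrogen-bond-family categories are mutually exclusive per pair.
    """
    criteria = criteria or InteractionCriteria()
    ctx = _Pairing(ligand, environment, typing, model)
    excluded = set(exclude_pairs or ())
    # pairs already claimed by hbond/weak_hbond are excluded from polar counts
    for env_atom in ctx.environment:
        if is_metal(env_atom) or is_water(env_atom):
            continue
        for lig_atom in ligand.atoms:
            if _classify_hbond(ctx, lig_atom, env_atom, criteria) is not None:
                excluded.add((lig_atom.serial, env_atom.serial))
    contacts = []
    for env_atom in ctx.environment:
        if is_metal(env_atom) or is_water(env_atom):
            continue
        ef = ctx.flags(env_atom, False)
        for lig_atom in ligand.atoms:
            if (lig_atom.serial, env_atom.serial) in excluded:
                continue
            lf = ctx.flags(lig_atom, True)
            if not ((lf.donor and ef.acceptor) or (ef.donor and lf.acceptor)):
                continue
            d = float(np.linalg.norm(lig_atom.coords - env_atom.coords))
            if d <= criteria.polar_dist_max:
                category = "polar"
            elif d <= criteria.weak_polar_dist_max:
                category = "weak_polar"
            else:
                continue
            contacts.append(Contact(lig_atom.name, _partner(env_atom), category, d))
    return _sorted(contacts)


def detect_vdw(ligand: LigandInstance, environment: Sequence[Atom],
               radii: dict[str, float] | None = None,
               criteria: InteractionCriteria | None = None,
               exclude_pairs: set | None = None,
               exclude_atoms: set | None = None) -> list[Contact]:
    """Van der Waals contacts and clashes from Bondi radii sums.

    A pair within r_A + r_B + slack is a vdw contact unless it penetrates to
    less than r_A + r_B - clash_overlap, which makes it a vdw_clash.
    ``exclude_atoms`` (serials) removes atoms engaged in hydrogen bonds, per
    the convention that vdW contacts hold between non-hydrogen-bonding atoms.
    """
    from .conformation import VDW_RADII

    criteria = criteria or InteractionCriteria()
    table = radii or VDW_RADII
    exclude_pairs = exclude_pairs or set()
    exclude_atoms = exclude_atoms or set()
    contacts = []
    for env_atom in environment:
        if is_metal(env_atom) or is_water(env_atom) or env_atom.serial in exclude_atoms:
            continue
        for lig_atom in ligand.atoms:
            if lig_atom.serial in exclude_atoms:
                continue
            if (lig_atom.serial, env_atom.serial) in exclude_pairs:
                continue
            try:
                rsum = table[lig_atom.element.upper()] + table[env_atom.element.upper()]
            except KeyError as exc:
                raise ValueError(f"no van der Waals radius for element {exc.args[0]!r}") from None
            d = float(np.linalg.norm(lig_atom.coords - env_atom.coords))
            if d > rsum + criteria.vdw_slack:
                continue
            category = "vdw_clash" if d < rsum - criteria.clash_overlap else "vdw"
            contacts.append(Contact(lig_atom.name, _partner(env_atom), category, d))
    return _sorted(contacts)


def detect_ionic(ligand: LigandInstance, environment: Sequence[Atom],
                 typing: AtomTyping | None = None,
                 criteria: InteractionCriteria | None = None) -> list[Contact]:
    """Cation-anion atom pairs within the ionic cutoff (default 4.0 Å)."""
    criteria = criteria or InteractionCriteria()
    ctx = _Pairing(ligand, environment, typing, None)
    contacts = []
    for env_atom in ctx.environment:
        if is_metal(env_atom) or is_water(env_atom):
            continue
        ef = ctx.flags(env_atom, False)
        for lig_atom in ligand.atoms:
            lf = ctx.flags(lig_atom, True)
            if not ((lf.anionic and ef.cationic) or (lf.cationic and ef.anionic)):
                continue
            d = float(np.linalg.norm(lig_atom.coords - env_atom.coords))
            if d <= criteria.ionic_dist_max:
                contacts.append(Contact(lig_atom.name, _partner(env_atom), "ionic", d))
    return _sorted(contacts)


def detect_metal(ligand: LigandInstance, environment: Sequence[Atom],
                 criteria: InteractionCriteria | None = None,
                 model: StructureModel | None = None) -> list[Contact]:
    """Metal coordination of ligand N/O atoms (default 3.0 Å) with bridging report.

    Each contact lists the protein-side N/O partners of the same metal as
    ``bridge_partners`` (a metal bridging ligand and protein).
    """
    criteria = criteria or InteractionCriteria()
    pool = list(model.atoms) if model is not None else list(environment)
    lig_serials = ligand.serials
    contacts = []
    for metal in environment:
        if not is_metal(metal):
            continue
        bridges = tuple(
            _partner(a) for a in pool
            if a.serial not in lig_serials and a.serial != metal.serial
            and not is_metal(a) and not is_water(a) and a.element.upper() in ("N", "O")
            and np.linalg.norm(a.coords - metal.coords) <= criteria.metal_dist_max)
        for lig_atom in ligand.atoms:
            if lig_atom.element.upper() not in ("N", "O"):
                continue
            d = float(np.linalg.norm(lig_atom.coords - metal.coords))
            if d <= criteria.metal_dist_max:
                contacts.append(Contact(lig_atom.name, _partner(metal), "metal", d,
                                        bridge_partners=bridges))
    return _sorted(contacts)


def _ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[-1]


def detect_aromatic(ligand: LigandInstance, environment: Sequence[Atom],
                    typing: AtomTyping | None = None,
                    criteria: InteractionCriteria | None = None,
                    model: StructureModel | None = None) -> list[Contact]:
    """Ring-stacking contacts between guanine rings and Phe/Tyr/Trp/His side chains.

    Ring centroids within 4.5 Å count as aromatic; the inter-normal angle
    subclasses the geometry as parallel (<= 30 degrees), T-shaped (>= 60) or
    inclined.  Partial side-chain rings missing atoms are completed from the
    full model when provided.
    """
    criteria = criteria or InteractionCriteria()
    pool = list(model.atoms) if model is not None else list(environment)
    lig_rings = []
    for names in (GUANINE_6RING, GUANINE_5RING):
        if all(ligand.has_atom(n) for n in names):
            lig_rings.append((names, ligand.coords_of(names)))
    env_residues: dict[tuple, list[Atom]] = {}
    for atom in environment:
        if atom.residue_name in PROTEIN_RINGS:
            env_residues.setdefault(
                (atom.chain_id, atom.residue_seq, atom.residue_name), []).append(atom)
    contacts = []
    for (chain, seq, resname), atoms in sorted(env_residues.items()):
        res_pool = [a for a in pool if (a.chain_id, a.residue_seq, a.residue_name)
                    == (chain, seq, resname)]
        by_name = {a.name: a for a in res_pool}
        for ring_names in PROTEIN_RINGS[resname]:
            if not all(n in by_name for n in ring_names):
                continue
            ring_atoms = [by_name[n] for n in ring_names]
            env_coords = np.array([a.coords for a in ring_atoms])
            env_centroid, env_normal = _ring_geometry(env_coords)
            for lig_names, lig_coords in lig_rings:
                lig_centroid, lig_normal = _ring_geometry(lig_coords)
                d = float(np.linalg.norm(lig_centroid - env_centroid))
                if d > criteria.aromatic_centroid_max:
                    continue
                cosang = abs(float(np.dot(lig_normal, env_normal)))
                angle = math.degrees(math.acos(min(1.0, cosang)))
                subtype = ("parallel" if angle <= 30.0
                           else "t_shaped" if angle >= 60.0 else "inclined")
                lig_rep = lig_names[int(np.argmin(
                    np.linalg.norm(lig_coords - env_centroid, axis=1)))]
                env_rep = ring_atoms[int(np.argmin(
                    np.linalg.norm(env_coords - lig_centroid, axis=1)))]
                contacts.append(Contact(lig_rep, _partner(env_rep), "aromatic", d,
                                        angle=angle, subtype=subtype))
    return _sorted(contacts)


def water_mediated_hbonds(ligand: LigandInstance, environment: Sequence[Atom],
                          typing: AtomTyping | None = None,
                          criteria: InteractionCriteria | None = None,
                          model: StructureModel | None = None) -> list[Contact]:
    """Water bridges: a water oxygen hydrogen-bonded to both ligand and protein.

    Returns one contact per (ligand atom, protein atom) pair sharing a water,
    flagged ``water_mediated`` with the water identity in ``via``; the
    recorded distance is the ligand-side leg.
    """
    criteria = criteria or InteractionCriteria()
    ctx = _Pairing(ligand, environment, typing, model)
    lo, hi = criteria.hbond_dist
    alo = criteria.hbond_angle[0]

    def leg_ok(polar_atom: Atom, water: Atom, on_ligand: bool) -> bool:
        flags = ctx.flags(polar_atom, on_ligand)
        if not (flags.donor or flags.acceptor):
            return False
        d = float(np.linalg.norm(polar_atom.coords - water.coords))
        if not lo <= d <= hi:
            return False
        if flags.acceptor:
            # water can always act as donor (no antecedent -> distance-only)
            return True
        angle = _donor_angle(polar_atom, water, ctx.pool)
        return angle is None or angle >= alo

    contacts = []
    lig_serials = ligand.serials
    for water in ctx.environment:
        if not is_water(water) or water.element.upper() != "O":
            continue
        lig_legs = [a for a in ligand.atoms if leg_ok(a, water, True)]
        prot_legs = [a for a in ctx.environment
                     if not is_water(a) and not is_metal(a) and a.serial not in lig_serials
                     and leg_ok(a, water, False)]
        for lig_atom in lig_legs:
            for prot_atom in prot_legs:
                contacts.append(Contact(
                    lig_atom.name, _partner(prot_atom), "hbond",
                    distance=float(np.linalg.norm(lig_atom.coords - water.coords)),
                    water_mediated=True, via=_partner(water)))
    return _sorted(contacts)


def _sorted(contacts: list[Contact]) -> list[Contact]:
    return sorted(contacts, key=lambda c: (c.ligand_atom, c.partner.chain,
                                           c.partner.residue_seq, c.partner.atom,
                                           c.category))


@dataclass
class Fingerprint:
    """Typed contact list of one complex with exact marginal counts."""

    pdb_id: str
    ligand_code: str
    contacts: list[Contact] = field(default_factory=list)
    water_bridges: list[Contact] = field(default_factory=list)

    @property
    def counts_by_category(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for contact in self.contacts:
            counts[contact.category] += 1
        return counts

    @property
    def counts_by_atom(self) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for contact in self.contacts:
            key = (contact.ligand_atom, contact.category)
            counts[key] = counts.get(key, 0) + 1
        return counts

    @property
    def total_contacts(self) -> int:
        return len(self.contacts)

    def to_dict(self) -> dict:
        def contact_dict(c: Contact) -> dict:
            return {
                "ligand_atom": c.ligand_atom, "partner": list(c.partner),
                "category": c.category, "distance": round(c.distance, 4),
                "angle": None if c.angle is None else round(c.angle, 2),
                "water_mediated": c.water_mediated, "subtype": c.subtype,
                "via": None if c.via is None else list(c.via),
            }
        return {"pdb_id": self.pdb_id, "ligand_code": self.ligand_code,
                "contacts": [contact_dict(c) for c in self.contacts],
                "water_bridges": [contact_dict(c) for c in self.water_bridges],
                "counts_by_category": self.counts_by_category}

    @classmethod
    def from_dict(cls, data: dict) -> "Fingerprint":
        def load_contact(d: dict) -> Contact:
            return Contact(
                ligand_atom=d["ligand_atom"], partner=Partner(*d["partner"]),
                category=d["category"], distance=d["distance"], angle=d.get("angle"),
                water_mediated=d.get("water_mediated", False), subtype=d.get("subtype"),
                via=Partner(*d["via"]) if d.get("via") else None)
        return cls(pdb_id=data["pdb_id"], ligand_code=data["ligand_code"],
                   contacts=[load_contact(c) for c in data["contacts"]],
                   water_bridges=[load_contact(c) for c in data.get("water_bridges", [])])

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def fingerprint_complex(model: StructureModel, ligand: LigandInstance,
                        typing: AtomTyping | None = None,
                        criteria: InteractionCriteria | None = None) -> Fingerprint:
    """Run all nine detectors inside the environment cutoff and assemble counts.

    Hierarchy making the counts a partition: metal coordination first; then
    cation-anion pairs are ionic only; remaining donor/acceptor pairs go to
    hbond > weak_hbond > polar > weak_polar; van der Waals contacts are
    computed between atoms not engaged in hydrogen bonding.  Water bridges
    are reported separately and never enter the nine marginal counts.
    """
    criteria = criteria or InteractionCriteria()
    typing = typing or assign_atom_types(model)
    env = select_environment(model, ligand, criteria.environment_cutoff)

    metal_contacts = detect_metal(ligand, env, criteria, model=model)
    ionic_contacts = detect_ionic(ligand, env, typing, criteria)
    ionic_pairs = {(ligand.atom(c.ligand_atom).serial, _serial_of(env, c.partner))
                   for c in ionic_contacts}

    hb = detect_hbonds(ligand, env, typing, criteria, model=model,
                       exclude_pairs=ionic_pairs)
    hb_pairs = {(ligand.atom(c.ligand_atom).serial, _serial_of(env, c.partner)) for c in hb}
    hb_atoms = {s for pair in hb_pairs for s in pair}

    polar = detect_polar(ligand, env, typing, criteria, model=model,
                         exclude_pairs=ionic_pairs | hb_pairs)
    polar_pairs = {(ligand.atom(c.ligand_atom).serial, _serial_of(env, c.partner))
                   for c in polar}

    vdw = detect_vdw(ligand, env, criteria=criteria,
                     exclude_pairs=ionic_pairs | hb_pairs | polar_pairs,
                     exclude_atoms=hb_atoms)
    aromatic = detect_aromatic(ligand, env, typing, criteria, model=model)
    bridges = water_mediated_hbonds(ligand, env, typing, criteria, model=model)

    contacts = _sorted(metal_contacts + ionic_contacts + hb + polar + vdw + aromatic)
    return Fingerprint(pdb_id=model.pdb_id, ligand_code=ligand.ligand_code,
                       contacts=contacts, water_bridges=bridges)


def _serial_of(environment: Sequence[Atom], partner: Partner) -> int:
    for a in environment:
        if _partner(a) == partner:
            return a.serial
    raise KeyError(partner)


def write_contacts_tsv(fingerprints: Iterable[Fingerprint], path=None,
                       header_lines: Sequence[str] = ()) -> str:
    """Tabular contact export (one row per contact, deterministic order)."""
    lines = [f"# {h}" for h in header_lines]
    lines.append("pdb_id\tligand_code\tligand_atom\tchain\tresseq\tresname\tatom\t"
                 "category\tdistance\tangle\twater_mediated")
    for fp in fingerprints:
        for c in list(fp.contacts) + list(fp.water_bridges):
            angle = "" if c.angle is None else f"{c.angle:.1f}"
            lines.append(f"{fp.pdb_id}\t{fp.ligand_code}\t{c.ligand_atom}\t"
                         f"{c.partner.chain}\t{c.partner.residue_seq}\t"
                         f"{c.partner.residue_name}\t{c.partner.atom}\t{c.category}\t"
                         f"{c.distance:.2f}\t{angle}\t{int(c.water_mediated)}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
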