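"""Independent brute-force re-implementations used as test oracles.

These deliberately avoid the package's detector code paths: plain nested
loops, explicit geometry, and a literal transcription of the contact rules.
Only the residue-template typing table is shared, since it is input data.
"""

import math

import numpy as np

from alarmone.conformation import VDW_RADII
from alarmone.structure_io import flags_for, is_metal, is_water


def angle_at(b, a, c):
    """Angle a-b-c in degrees (vertex at b)."""
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def dihedral_reference(p1, p2, p3, p4):
    """Torsion angle by the atan2 cross-product formula (independent route)."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))


def _flags(atom, ligand_code=None):
    residue = ligand_code if ligand_code is not None else atom.residue_name
    return flags_for(residue, atom.name, atom.element)


def _antecedents(atom, pool):
    out = []
    for other in pool:
        if other.serial == atom.serial or other.element.upper() == "H":
            continue
        if (other.chain_id, other.residue_seq) != (atom.chain_id, atom.residue_seq):
            continue
        cut = 1.95 if "P" in (atom.element, other.element) or "S" in (
            atom.element, other.element) else 1.85
        if 0.4 < np.linalg.norm(other.coords - atom.coords) <= cut:
            out.append(other)
    return out


def brute_force_pairs(model, ligand, criteria):
    """Exhaustive all-pairs contact typing following the stated rules.

    Returns {category: set((ligand_atom_name, env_serial))} applying the same
    hierarchy as the pipeline: metal first, cation-anion pairs are ionic
    only, then hbond > weak_hbond > polar > weak_polar, and van der Waals
    contacts between atoms not engaged in hydrogen bonds.
    """
    lig_serials = {a.serial for a in ligand.atoms}
    env = []
    for a in model.atoms:
        if a.serial in lig_serials:
            continue
        dmin = min(np.linalg.norm(a.coords - b.coords) for b in ligand.atoms)
        if dmin <= criteria.environment_cutoff:
            env.append(a)
    pool = list(model.atoms)

    out = {c: set() for c in ("metal", "ionic", "hbond", "weak_hbond",
                              "polar", "weak_polar", "vdw", "vdw_clash")}
    claimed = set()

    for e in env:
        if not is_metal(e):
            continue
        for la in ligand.atoms:
            if la.element in ("N", "O") and \
                    np.linalg.norm(la.coords - e.coords) <= criteria.metal_dist_max:
                out["metal"].add((la.name, e.serial))

    for e in env:
        if is_metal(e) or is_water(e):
            continue
        ef = _flags(e)
        for la in ligand.atoms:
            lf = _flags(la, ligand.ligand_code)
            d = float(np.linalg.norm(la.coords - e.coords))
            key = (la.name, e.serial)
            if ((lf.anionic and ef.cationic) or (lf.cationic and ef.anionic)) \
                    and d <= criteria.ionic_dist_max:
                out["ionic"].add(key)
                claimed.add(key)

    hb_atoms = set()
    for e in env:
        if is_metal(e) or is_water(e):
            continue
        ef = _flags(e)
        for la in ligand.atoms:
            key = (la.name, e.serial)
            if key in claimed:
                continue
            lf = _flags(la, ligand.ligand_code)
            pair_da = (lf.donor and ef.acceptor) or (ef.donor and lf.acceptor)
            if not pair_da:
                continue
            d = float(np.linalg.norm(la.coords - e.coords))
            if d > criteria.weak_polar_dist_max:
                continue
            angles = []
            if lf.donor and ef.acceptor:
                angles += [angle_at(la.coords, x.coords, e.coords)
                           for x in _antecedents(la, pool)]
            if ef.donor and lf.acceptor:
                angles += [angle_at(e.coords, x.coords, la.coords)
                           for x in _antecedents(e, pool)]
            best = max(angles) if angles else None
            lo, hi = criteria.hbond_dist
            if lo <= d <= hi and (best is None or best >= criteria.hbond_angle[0]):
                cat = "hbond"
            elif d < criteria.weak_hbond_dist_max and \
                    (best is None or best < criteria.weak_hbond_angle_max):
                cat = "weak_hbond"
            elif d <= criteria.polar_dist_max:
                cat = "polar"
            else:
                cat = "weak_polar"
            out[cat].add(key)
            claimed.add(key)
            if cat in ("hbond", "weak_hbond"):
                hb_atoms.add(la.name)
                hb_atoms.add(e.serial)

    for e in env:
        if is_metal(e) or is_water(e) or e.serial in hb_atoms:
            continue
        for la in ligand.atoms:
            if la.name in hb_atoms:
                continue
            key = (la.name, e.serial)
            if key in claimed:
                continue
            rsum = VDW_RADII[la.element.upper()] + VDW_RADII[e.element.upper()]
            d = float(np.linalg.norm(la.coords - e.coords))
            if d <= rsum + criteria.vdw_slack:
                cat = "vdw_clash" if d < rsum - criteria.clash_overlap else "vdw"
                out[cat].add(key)
    return out
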