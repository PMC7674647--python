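"""Contact-detector unit tests with planted geometries plus oracle checks."""

import math

import numpy as np
import pytest
import yaml

from alarmone.interactions import (
    CATEGORIES,
    Contact,
    Fingerprint,
    InteractionCriteria,
    Partner,
    detect_aromatic,
    detect_hbonds,
    detect_ionic,
    detect_metal,
    detect_polar,
    detect_vdw,
    fingerprint_complex,
    water_mediated_hbonds,
    write_contacts_tsv,
)
from alarmone.structure_io import (
    Atom,
    LigandInstance,
    StructureModel,
    assign_atom_types,
    select_environment,
)
from alarmone.synthetic import build_corpus, build_water_bridge_site
from oracles import brute_force_pairs

CRIT = InteractionCriteria()


def _atom(serial, name, element, resname, xyz, chain="B", resseq=101, hetero=False):
    return Atom(serial, name, element, resname, resseq, chain,
                np.asarray(xyz, float), is_hetero=hetero)


def _micro_ligand(extra=()):
    """Guanine N2 donor with its C2 antecedent (fragment ligand)."""
    atoms = [_atom(1, "C2", "C", "G4P", (0, 0, 0), chain="A", resseq=1, hetero=True),
             _atom(2, "N2", "N", "G4P", (1.34, 0, 0), chain="A", resseq=1, hetero=True)]
    atoms += list(extra)
    return LigandInstance("G4P", atoms, completeness={"fragment": True})


def _partner_at(distance, angle, serial=10, name="OD1", element="O", resname="ASN"):
    """Acceptor placed at (distance, donor angle) from the N2 donor above."""
    phi = math.radians(180.0 - angle)
    pos = np.array([1.34, 0, 0]) + distance * np.array(
        [math.cos(phi), math.sin(phi), 0.0])
    return _atom(serial, name, element, resname, pos)


class TestHbondDetector:
    def test_canonical_hbond(self):
        lig = _micro_ligand()
        env = [_partner_at(3.0, 160.0)]
        (c,) = detect_hbonds(lig, env)
        assert c.category == "hbond"
        assert c.distance == pytest.approx(3.0)
        assert c.angle == pytest.approx(160.0)

    def test_short_low_angle_is_weak(self):
        lig = _micro_ligand()
        (c,) = detect_hbonds(lig, [_partner_at(2.5, 100.0)])
        assert c.category == "weak_hbond"

    def test_beyond_window_is_nothing(self):
        lig = _micro_ligand()
        assert detect_hbonds(lig, [_partner_at(3.8, 160.0)]) == []

    def test_no_antecedent_falls_back_to_distance(self):
        # a lone water-like donor against the ligand acceptor N3
        lig = LigandInstance("G4P", [
            _atom(1, "N3", "N", "G4P", (0, 0, 0), chain="A", resseq=1, hetero=True)],
            completeness={"fragment": True})
        env = [_atom(10, "O", "O", "HOH", (3.0, 0, 0), hetero=True)]
        (c,) = detect_hbonds(lig, env, include_waters=True)
        assert c.category == "hbond" and c.angle is None

    def test_distance_window_monotonicity(self, nine_category_complex):
        model, ligand, _ = nine_category_complex
        typing = assign_atom_types(model)
        env = select_environment(model, ligand, 5.0)
        base = sum(c.category == "hbond"
                   for c in detect_hbonds(ligand, env, typing, CRIT, model=model))
        wide = InteractionCriteria(hbond_dist=(2.4, 3.8))
        more = sum(c.category == "hbond"
                   for c in detect_hbonds(ligand, env, typing, wide, model=model))
        assert more >= base >= 1


class TestPolarDetector:
    def test_bad_angle_polar_not_weak_hbond(self):
        # fails the hbond angle window but sits inside the polar distance
        lig = _micro_ligand()
        env = [_partner_at(3.4, 95.0)]
        assert detect_hbonds(lig, env) == []
        (c,) = detect_polar(lig, env)
        assert c.category == "polar"

    def test_weak_polar_band(self):
        lig = _micro_ligand()
        (c,) = detect_polar(lig, [_partner_at(3.8, 160.0)])
        assert c.category == "weak_polar"

    def test_hbond_pair_not_double_counted(self):
        lig = _micro_ligand()
        env = [_partner_at(3.0, 160.0)]
        assert detect_polar(lig, env) == []


class TestVdwDetector:
    def _carbon_pair(self, d):
        lig = LigandInstance("G4P", [
            _atom(1, "C8", "C", "G4P", (0, 0, 0), chain="A", resseq=1, hetero=True)],
            completeness={"fragment": True})
        env = [_atom(10, "OD1", "O", "ASN", (d, 0, 0))]
        return lig, env

    def test_bondi_sum_window(self):
        # C...O: 1.70 + 1.52 = 3.22, slack 0.1
        lig, env = self._carbon_pair(3.2)
        (c,) = detect_vdw(lig, env)
        assert c.category == "vdw"

    def test_penetration_is_clash(self):
        lig, env = self._carbon_pair(2.5)  # < 3.22 - 0.4
        (c,) = detect_vdw(lig, env)
        assert c.category == "vdw_clash"

    def test_beyond_radii_sum(self):
        lig, env = self._carbon_pair(3.5)
        assert detect_vdw(lig, env) == []

    def test_missing_radius_rejected(self):
        lig = LigandInstance("G4P", [
            _atom(1, "X1", "XX", "G4P", (0, 0, 0), chain="A", resseq=1, hetero=True)],
            completeness={"fragment": True})
        env = [_atom(10, "CA", "C", "GLY", (3.0, 0, 0))]
        with pytest.raises(ValueError, match="radius"):
            detect_vdw(lig, env)


class TestIonicDetector:
    def _phosphate_fragment(self):
        return LigandInstance("G4P", [
            _atom(1, "PD", "P", "G4P", (0, 0, 0), chain="A", resseq=1, hetero=True),
            _atom(2, "O1D", "O", "G4P", (1.48, 0, 0), chain="A", resseq=1, hetero=True)],
            completeness={"fragment": True})

    @pytest.mark.parametrize("d,name,resname,expect", [
        (3.5, "NH1", "ARG", 1), (4.5, "NH1", "ARG", 0), (3.9, "NZ", "LYS", 1)])
    def test_cation_anion_window(self, d, name, resname, expect):
        lig = self._phosphate_fragment()
        env = [_atom(10, name, "N", resname, (1.48 + d, 0, 0))]
        assert len(detect_ionic(lig, env)) == expect


class TestMetalDetector:
    def _fragment(self):
        return LigandInstance("G4P", [
            _atom(1, "PB", "P", "G4P", (0, 0, 0), chain="A", resseq=1, hetero=True),
            _atom(2, "O1B", "O", "G4P", (1.48, 0, 0), chain="A", resseq=1, hetero=True)],
            completeness={"fragment": True})

    def test_coordination_window(self):
        lig = self._fragment()
        hits = detect_metal(lig, [_atom(10, "MG", "MG", "MG", (3.58, 0, 0), hetero=True)])
        assert len(hits) == 1 and hits[0].ligand_atom == "O1B"
        assert detect_metal(lig, [_atom(10, "MG", "MG", "MG", (4.98, 0, 0),
                                        hetero=True)]) == []

    def test_bridge_report(self):
        lig = self._fragment()
        mg = _atom(10, "MG", "MG", "MG", (3.58, 0, 0), hetero=True)
        asp = _atom(11, "OD1", "O", "ASP", (5.78, 0, 0))
        (c,) = detect_metal(lig, [mg, asp])
        assert c.bridge_partners == (Partner("B", 101, "ASP", "OD1"),)


class TestAromaticDetector:
    def _tyr_ring(self, center, normal, serial0=20, resseq=130):
        normal = np.asarray(normal, float)
        normal = normal / np.linalg.norm(normal)
        ref = np.array([1.0, 0, 0]) if abs(normal[0]) < 0.9 else np.array([0, 1.0, 0])
        e1 = np.cross(normal, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        return [_atom(serial0 + k, n, "C", "TYR",
                      np.asarray(center) + 1.38 * (math.cos(2 * math.pi * k / 6) * e1
                                                   + math.sin(2 * math.pi * k / 6) * e2),
                      resseq=resseq)
                for k, n in enumerate(names)]

    def test_parallel_stack(self, ppgpp):
        from alarmone.structure_io import GUANINE_6RING
        ring = ppgpp.coords_of(GUANINE_6RING)
        centroid = ring.mean(axis=0)
        normal = np.linalg.svd(ring - centroid)[2][-1]
        env = self._tyr_ring(centroid + 3.6 * normal, normal)
        hits = detect_aromatic(ppgpp, env)
        assert any(c.subtype == "parallel" and c.distance == pytest.approx(3.6, abs=0.01)
                   for c in hits)

    def test_far_centroid_no_contact(self, ppgpp):
        from alarmone.structure_io import GUANINE_6RING
        ring = ppgpp.coords_of(GUANINE_6RING)
        centroid = ring.mean(axis=0)
        normal = np.linalg.svd(ring - centroid)[2][-1]
        env = self._tyr_ring(centroid + 5.5 * normal, normal)
        assert detect_aromatic(ppgpp, env) == []

    def test_perpendicular_ring_is_t_shaped(self, ppgpp):
        from alarmone.structure_io import GUANINE_6RING
        ring = ppgpp.coords_of(GUANINE_6RING)
        centroid = ring.mean(axis=0)
        normal = np.linalg.svd(ring - centroid)[2][-1]
        perp = np.cross(normal, [1.0, 0, 0])
        perp /= np.linalg.norm(perp)
        env = self._tyr_ring(centroid + 4.4 * normal, perp)
        hits = detect_aromatic(ppgpp, env)
        assert any(c.subtype == "t_shaped" for c in hits)


class TestWaterBridges:
    def test_single_bridge(self, ppgpp):
        model = build_water_bridge_site(ppgpp)
        env = select_environment(model, ppgpp, 5.0)
        bridges = water_mediated_hbonds(ppgpp, env, assign_atom_types(model), model=model)
        assert len(bridges) == 1
        assert bridges[0].water_mediated and bridges[0].via.residue_name == "HOH"

    def test_two_independent_bridges(self, ppgpp):
        model = build_water_bridge_site(ppgpp, n_bridges=2)
        env = select_environment(model, ppgpp, 5.0)
        bridges = water_mediated_hbonds(ppgpp, env, assign_atom_types(model), model=model)
        assert len(bridges) == 2

    def test_water_bonded_only_to_ligand(self, ppgpp):
        o6 = ppgpp.atom("O6").coords
        away = o6 - ppgpp.atom("C6").coords
        away /= np.linalg.norm(away)
        water = _atom(900, "O", "O", "HOH", o6 + 2.9 * away, chain="W",
                      resseq=301, hetero=True)
        model = StructureModel("W1", 0, list(ppgpp.atoms) + [water])
        env = select_environment(model, ppgpp, 5.0)
        assert water_mediated_hbonds(ppgpp, env, assign_atom_types(model),
                                     model=model) == []


class TestCriteriaConfig:
    def test_unknown_key_named(self):
        with pytest.raises(KeyError, match="hbond_distance"):
            InteractionCriteria.from_dict({"hbond_distance": 3.0})

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "crit.yaml"
        path.write_text(yaml.safe_dump({"ionic_dist_max": 4.5,
                                        "hbond_dist": [2.7, 3.6]}))
        crit = InteractionCriteria.from_yaml(path)
        assert crit.ionic_dist_max == 4.5
        assert crit.hbond_dist == (2.7, 3.6)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            InteractionCriteria(ionic_dist_max=-1.0)


class TestFingerprint:
    def test_nine_planted_categories_all_recovered(self, nine_category_complex):
        model, ligand, spec = nine_category_complex
        fp = fingerprint_complex(model, ligand)
        expected = {c: 0 for c in CATEGORIES}
        expected.update(spec.expected_counts)
        assert fp.counts_by_category == expected

    def test_empty_environment_all_zero(self, ppgpp):
        model = StructureModel("EMPTY", 0, list(ppgpp.atoms))
        fp = fingerprint_complex(model, ppgpp)
        assert fp.total_contacts == 0
        assert set(fp.counts_by_category.values()) == {0}

    def test_counts_are_exact_marginals(self, nine_category_complex):
        model, ligand, _ = nine_category_complex
        fp = fingerprint_complex(model, ligand)
        assert sum(fp.counts_by_category.values()) == len(fp.contacts)
        assert sum(fp.counts_by_atom.values()) == len(fp.contacts)

    def test_category_exclusivity_per_pair(self, nine_category_complex):
        model, ligand, _ = nine_category_complex
        fp = fingerprint_complex(model, ligand)
        hb_family, vdw_family = {}, {}
        for c in fp.contacts:
            key = (c.ligand_atom, c.partner)
            if c.category in ("hbond", "weak_hbond", "polar", "weak_polar"):
                assert key not in hb_family
                hb_family[key] = c.category
            if c.category in ("vdw", "vdw_clash"):
                assert key not in vdw_family
                vdw_family[key] = c.category
        assert not set(hb_family) & set(vdw_family)

    def test_three_hbonds_atom_marginal(self, ppgpp):
        # donors/acceptors N1, N2, O6 each receive exactly one hydrogen bond
        def along(from_name, to_name, d):
            a, b = ppgpp.atom(from_name).coords, ppgpp.atom(to_name).coords
            u = b - a
            return b + d * u / np.linalg.norm(u)

        n1_pos = along("C6", "N1", 0.0)  # recompute direction from bisector below
        c2, c6 = ppgpp.atom("C2").coords, ppgpp.atom("C6").coords
        n1 = ppgpp.atom("N1").coords
        bis = (n1 - c2) / np.linalg.norm(n1 - c2) + (n1 - c6) / np.linalg.norm(n1 - c6)
        bis /= np.linalg.norm(bis)
        partners = [
            _atom(900, "OD1", "O", "ASN", n1 + 3.0 * bis, resseq=150),
            _atom(901, "OD1", "O", "ASN", along("C2", "N2", 3.0), resseq=151),
            _atom(902, "ND2", "N", "ASN", along("C6", "O6", 3.0), resseq=152),
        ]
        # give the O6 partner an antecedent so its donor angle resolves
        ce = partners[2].coords + 1.3 * (partners[2].coords - ppgpp.atom("O6").coords) \
            / 3.0
        partners.append(_atom(903, "CG", "C", "ASN", ce, resseq=152))
        model = StructureModel("HB3", 0, list(ppgpp.atoms) + partners)
        fp = fingerprint_complex(model, ppgpp)
        hb_by_atom = {atom: n for (atom, cat), n in fp.counts_by_atom.items()
                      if cat == "hbond"}
        assert hb_by_atom == {"N1": 1, "N2": 1, "O6": 1}

    def test_json_roundtrip(self, nine_category_complex):
        model, ligand, _ = nine_category_complex
        fp = fingerprint_complex(model, ligand)
        back = Fingerprint.from_dict(__import__("json").loads(fp.to_json()))
        assert back.counts_by_category == fp.counts_by_category
        assert [(c.ligand_atom, c.partner, c.category) for c in back.contacts] == \
               [(c.ligand_atom, c.partner, c.category) for c in fp.contacts]
        for a, b in zip(back.contacts, fp.contacts):
            assert a.distance == pytest.approx(b.distance, abs=1e-3)

    def test_contacts_tsv_deterministic(self, nine_category_complex):
        model, ligand, _ = nine_category_complex
        fp = fingerprint_complex(model, ligand)
        assert write_contacts_tsv([fp]) == write_contacts_tsv([fp])
        assert len(write_contacts_tsv([fp]).splitlines()) == 1 + fp.total_contacts


class TestBruteForceOracle:
    def test_nine_category_fixture_matches_oracle(self, nine_category_complex):
        model, ligand, _ = nine_category_complex
        self._compare(model, ligand)

    def test_corpus_complexes_match_oracle(self):
        for cpx in build_corpus(n_per_class=1, seed=5):
            self._compare(cpx.model, cpx.ligand)

    @staticmethod
    def _compare(model, ligand):
        assert len(model.atoms) <= 200
        fp = fingerprint_complex(model, ligand)
        oracle = brute_force_pairs(model, ligand, CRIT)
        got = {c: set() for c in oracle}
        for contact in fp.contacts:
            if contact.category == "aromatic":
                continue  # ring-level, not pairwise
            serial = next(a.serial for a in model.atoms
                          if (a.chain_id, a.residue_seq, a.residue_name, a.name)
                          == tuple(contact.partner))
            got[contact.category].add((contact.ligand_atom, serial))
        assert got == oracle
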