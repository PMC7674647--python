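"""Torsion, pseudorotation, classification and ensemble-descriptor tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alarmone.conformation import (
    ConformerEnsemble,
    classify_glycosidic,
    compute_torsions,
    count_intramolecular_hbonds,
    dihedral,
    ideal_ring_torsions,
    kabsch_superpose,
    pseudorotation,
    radius_of_gyration,
    rmsf,
    sasa,
    torsion_distribution,
    analyze_torsion_table,
)
from alarmone.structure_io import Atom, LigandInstance, StructureModel, write_pdb
from conftest import REPORTED_CONFORMERS
from oracles import dihedral_reference

finite = st.floats(-50, 50, allow_nan=False)
point = st.tuples(finite, finite, finite)


class TestDihedral:
    def test_cis_is_zero(self):
        assert dihedral((1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, 1, 0)) == pytest.approx(0.0)

    def test_trans_is_180(self):
        assert abs(dihedral((1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, -1, 0))) == pytest.approx(180.0)

    def test_sign_convention_against_vector_oracle(self):
        quad = ((1, 0, 0), (0, 0, 0), (0, 0, 1),
                (math.cos(math.radians(100)), math.sin(math.radians(100)), 1))
        assert dihedral(*quad) == pytest.approx(-100.0)
        assert dihedral(*quad) == pytest.approx(dihedral_reference(*quad))

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    @settings(max_examples=50, derandomize=True)
    @given(p1=point, p2=point, p3=point, p4=point)
    def test_reversal_symmetry_and_mirror_antisymmetry(self, p1, p2, p3, p4):
        # the torsion angle is invariant under order reversal and negated by
        # reflection; skip degenerate (near-collinear) quadruples
        try:
            fwd = dihedral(p1, p2, p3, p4)
        except ValueError:
            return
        assert dihedral(p4, p3, p2, p1) == pytest.approx(fwd, abs=1e-6)
        mirror = [(-x, y, z) for x, y, z in (p1, p2, p3, p4)]
        assert abs(dihedral(*mirror)) == pytest.approx(abs(fwd), abs=1e-6)
        if abs(abs(fwd) - 180.0) > 1e-6 and abs(fwd) > 1e-9:
            assert dihedral(*mirror) == pytest.approx(-fwd, abs=1e-6)
        assert dihedral(p1, p2, p3, p4) == pytest.approx(dihedral_reference(p1, p2, p3, p4),
                                                         abs=1e-6)


class TestPseudorotation:
    @pytest.mark.parametrize("row", REPORTED_CONFORMERS.values(),
                             ids=list(REPORTED_CONFORMERS))
    def test_published_conformers_reproduced(self, row):
        pk = pseudorotation(row["nu"])
        assert pk.P == pytest.approx(row["P"], abs=0.02)
        assert pk.nu_max == pytest.approx(row["nu_max"], abs=0.02)
        assert pk.pucker_class == row["pucker"]

    def test_ideal_symmetric_case(self):
        pk = pseudorotation(ideal_ring_torsions(0.0, 40.0))
        assert pk.P % 360.0 == pytest.approx(0.0, abs=1e-9)
        assert pk.nu_max == pytest.approx(40.0, abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(P=st.floats(0, 359.999), nu_max=st.floats(5.001, 59.999))
    def test_ideal_roundtrip_exact(self, P, nu_max):
        pk = pseudorotation(ideal_ring_torsions(P, nu_max))
        assert abs((pk.P - P + 180.0) % 360.0 - 180.0) < 1e-6
        assert pk.nu_max == pytest.approx(nu_max, abs=1e-6)

    @pytest.mark.parametrize("P", [90.0, 270.0])
    def test_nu2_zero_limit(self, P):
        nu = ideal_ring_torsions(P, 38.0)
        assert abs(nu[2]) < 1e-9
        pk = pseudorotation(nu)
        assert pk.P == pytest.approx(P, abs=1e-6)
        assert pk.nu_max == pytest.approx(38.0, abs=1e-3)

    def test_planar_ring_rejected(self):
        with pytest.raises(ValueError, match="planar"):
            pseudorotation([0, 0, 0, 0, 0])

    def test_hemisphere_convention(self):
        assert pseudorotation(ideal_ring_torsions(18, 38)).hemisphere == "north"
        assert pseudorotation(ideal_ring_torsions(162, 38)).hemisphere == "south"
        assert pseudorotation(ideal_ring_torsions(300, 38)).hemisphere == "north"


class TestGlycosidic:
    @pytest.mark.parametrize("chi,label", [
        (-99.58, "anti"),   # -99.58 == 260.42 degrees
        (-116.08, "anti"), (-112.79, "anti"), (171.65, "anti"),
        (84.22, "syn"), (65.89, "syn"),
        (90.0, "anti"), (270.0, "syn"), (-90.0, "syn"), (0.0, "syn"),
    ])
    def test_syn_anti_ranges(self, chi, label):
        assert classify_glycosidic(chi).label == label

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_glycosidic(float("nan"))


class TestTorsionDistribution:
    def test_single_bin(self):
        hist = torsion_distribution([45.0] * 100, 10.0)
        assert hist.max() == pytest.approx(100.0)
        assert hist.sum() == pytest.approx(100.0)

    def test_uniform_grid(self):
        series = np.linspace(-179.5, 179.5, 360)
        hist = torsion_distribution(series, 10.0)
        np.testing.assert_allclose(hist.values, 100.0 / 36, rtol=1e-9)

    def test_bad_bin_width_and_empty(self):
        with pytest.raises(ValueError):
            torsion_distribution([1.0], 7.0)
        with pytest.raises(ValueError):
            torsion_distribution([], 10.0)


class TestEnsembleDescriptors:
    def test_rmsf_identical_frames_zero(self):
        ens = ConformerEnsemble(np.zeros((4, 3, 3)))
        np.testing.assert_allclose(rmsf(ens), 0.0)

    def test_rmsf_alternating_displacement(self):
        coords = np.zeros((10, 1, 3))
        coords[::2, 0, 0] = 0.7
        coords[1::2, 0, 0] = -0.7
        assert rmsf(ConformerEnsemble(coords))[0] == pytest.approx(0.7)

    def test_rmsf_matches_brute_force(self):
        rng = np.random.default_rng(42)
        coords = rng.normal(size=(100, 5, 3))
        got = rmsf(ConformerEnsemble(coords))
        mean = coords.mean(axis=0)
        expect = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
        np.testing.assert_allclose(got, expect)

    def test_rmsf_needs_two_frames(self):
        with pytest.raises(ValueError):
            rmsf(ConformerEnsemble(np.zeros((1, 3, 3))))

    def test_rgyr_cases(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]]) == 0.0
        assert radius_of_gyration([[0, 0, 0], [2, 0, 0]]) == pytest.approx(1.0)
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 3))
        com = pts.mean(axis=0)
        expect = math.sqrt(np.mean(np.sum((pts - com) ** 2, axis=1)))
        assert radius_of_gyration(pts) == pytest.approx(expect)

    def test_multi_model_pdb_roundtrip(self, ppgpp):
        m0 = StructureModel("E", 0, list(ppgpp.atoms))
        shifted = [Atom(a.serial, a.name, a.element, a.residue_name, a.residue_seq,
                        a.chain_id, a.coords + [0.5, 0, 0], a.occupancy, a.is_hetero)
                   for a in ppgpp.atoms]
        m1 = StructureModel("E", 1, shifted)
        ens = ConformerEnsemble.from_pdb(write_pdb([m0, m1]))
        assert ens.n_frames == 2 and ens.n_atoms == len(ppgpp.atoms)
        np.testing.assert_allclose(rmsf(ens), 0.25, atol=1e-9)


class TestSASA:
    def test_isolated_atom_analytic_sphere(self):
        per_atom, total = sasa(([[0, 0, 0]], ["O"]))
        analytic = 4 * math.pi * (1.52 + 1.4) ** 2
        assert total == pytest.approx(analytic, rel=0.01)
        assert per_atom[0] == total

    def test_fully_overlapping_pair_counts_once(self):
        _, total = sasa(([[0, 0, 0], [0, 0, 0.001]], ["O", "O"]))
        analytic = 4 * math.pi * (1.52 + 1.4) ** 2
        assert total == pytest.approx(analytic, rel=0.01)

    def test_distant_pair_is_additive(self):
        _, total = sasa(([[0, 0, 0], [50, 0, 0]], ["O", "C"]))
        analytic = 4 * math.pi * ((1.52 + 1.4) ** 2 + (1.70 + 1.4) ** 2)
        assert total == pytest.approx(analytic, rel=0.01)

    def test_rigid_rotation_invariance(self, ppgpp):
        coords = np.array([a.coords for a in ppgpp.atoms])
        elements = [a.element for a in ppgpp.atoms]
        _, t0 = sasa((coords, elements))
        theta = math.radians(37.0)
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0], [0, 0, 1.0]])
        _, t1 = sasa((coords @ R.T + 3.0, elements))
        assert t1 == pytest.approx(t0, rel=0.02)

    def test_missing_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            sasa(([[0, 0, 0]], ["XX"]))


def _mini_ligand(atom_specs):
    atoms = [Atom(i + 1, name, elem, "G4P", 1, "A", np.asarray(xyz, float),
                  is_hetero=True)
             for i, (name, elem, xyz) in enumerate(atom_specs)]
    return LigandInstance("G4P", atoms, completeness={"fragment": True})


class TestIntramolecularHBonds:
    def test_extended_fragment_has_none(self):
        lig = _mini_ligand([("C2'", "C", (0, 0, 0)), ("O2'", "O", (1.41, 0, 0)),
                            ("O6", "O", (8.0, 0, 0))])
        assert count_intramolecular_hbonds(lig) == 0

    def test_single_planted_donor_acceptor(self):
        # O2'(H)...O6 at 3.0 Å with a 150 degree antecedent angle
        c2 = np.array([0.0, 0.0, 0.0])
        o2 = np.array([1.41, 0.0, 0.0])
        phi = math.radians(180 - 150)
        o6 = o2 + 3.0 * np.array([math.cos(phi), math.sin(phi), 0.0])
        lig = _mini_ligand([("C2'", "C", c2), ("O2'", "O", o2), ("O6", "O", o6)])
        assert count_intramolecular_hbonds(lig) == 1

    def test_two_planted_pairs(self):
        c2 = np.array([0.0, 0.0, 0.0])
        o2 = np.array([1.41, 0.0, 0.0])
        phi = math.radians(30)
        o6 = o2 + 3.0 * np.array([math.cos(phi), math.sin(phi), 0.0])
        c2b = np.array([0.0, 0.0, 9.0])
        n2 = c2b + np.array([1.34, 0.0, 0.0])
        o1a = n2 + 3.0 * np.array([math.cos(phi), math.sin(phi), 0.0])
        lig = _mini_ligand([("C2'", "C", c2), ("O2'", "O", o2), ("O6", "O", o6),
                            ("C2", "C", c2b), ("N2", "N", n2), ("O1A", "O", o1a)])
        assert count_intramolecular_hbonds(lig) == 2

    def test_short_bond_separation_excluded(self):
        # O2' and O3' on adjacent carbons are 1-4... but placed 2 bonds apart here
        lig = _mini_ligand([("C2'", "C", (0, 0, 0)), ("O2'", "O", (1.41, 0, 0)),
                            ("O3'", "O", (0.1, 1.40, 0))])
        # O2'-C2'-O3': two bonds apart, inside the window but excluded
        assert count_intramolecular_hbonds(lig) == 0


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_rotated_copy_zero_rmsd(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        theta = math.radians(72)
        R0 = np.array([[math.cos(theta), -math.sin(theta), 0],
                       [math.sin(theta), math.cos(theta), 0], [0, 0, 1.0]])
        moved = pts @ R0.T + [1.0, -2.0, 0.5]
        R, t, rmsd = kabsch_superpose(pts, moved)
        assert rmsd < 1e-6
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_displaced_atom_matches_numerical_optimizer(self):
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        target = rng.normal(size=(10, 3))
        mobile = target.copy()
        mobile[0] += [1.0, 0, 0]

        def cost(x):
            R = Rotation.from_rotvec(x[:3]).as_matrix()
            return np.sum((mobile @ R.T + x[3:] - target) ** 2)

        best = min((minimize(cost, x0, method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
                    for x0 in (np.zeros(6), np.r_[0.3, -0.2, 0.1, 0.5, 0.5, -0.5])),
                   key=lambda r: r.fun)
        _, _, rmsd = kabsch_superpose(mobile, target)
        assert rmsd == pytest.approx(math.sqrt(best.fun / 10), abs=1e-5)

    def test_degenerate_input_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestLigandTorsions:
    def test_missing_atom_names_torsion(self, ppgpp):
        partial = LigandInstance(
            "G4P", [a for a in ppgpp.atoms if a.name != "C4"],
            completeness={"fragment": True})
        with pytest.raises(ValueError, match="chi"):
            compute_torsions(partial)

    def test_torsion_table_roundtrip(self):
        import pandas as pd
        df = pd.DataFrame([{"id": k, **{f"nu{j}": row["nu"][j] for j in range(5)},
                            "chi": row["chi"], "gamma": 0.0}
                           for k, row in REPORTED_CONFORMERS.items()])
        out = analyze_torsion_table(df)
        for _, rec in out.iterrows():
            row = REPORTED_CONFORMERS[rec["id"]]
            assert rec["P"] == pytest.approx(row["P"], abs=0.02)
            assert rec["pucker_class"] == row["pucker"]
            assert rec["glycosidic_class"] == row["glyc"]
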