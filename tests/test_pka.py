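import numpy as np
import pytest

from protdepth import (PkaFeatures, PkaModel, asa_shrake_rupley,
                       compute_features, detect_hbonds,
                       electrostatic_energy, evaluate_rmsd,
                       fit_coefficients, make_fixture, predict_pka)
from protdepth.pka import COULOMB_K
from protdepth.solvation import SolvationConfig, compute_depth
from protdepth.structures import Structure

from conftest import micro_structure
from oracles import rmsd_loops

MODEL = PkaModel.default()


def carboxylate_probe(dist, angle_deg):
    """ASP carboxylate oxygen plus a backbone amide donor at a given
    distance and donor-acceptor-antecedent angle."""
    th = np.radians(angle_deg)
    n_pos = dist * np.array([-np.cos(th), np.sin(th), 0.0])
    return micro_structure([
        ("A", 1, "ASP", [("OD1", "O", [0, 0, 0]),
                         ("CG", "C", [-1.25, 0, 0])]),
        ("A", 2, "GLY", [("N", "N", n_pos),
                         ("CA", "C", n_pos + [0, 1.5, 0])]),
    ])


class TestDetectHbonds:
    def test_bond_within_both_thresholds(self):
        st = carboxylate_probe(3.4, 120)
        group = [st.residue("A", 1).atom("OD1")]
        assert detect_hbonds(st, group) == 1

    def test_distance_rule(self):
        st = carboxylate_probe(3.6, 120)
        group = [st.residue("A", 1).atom("OD1")]
        assert detect_hbonds(st, group) == 0

    def test_angle_rule(self):
        st = carboxylate_probe(3.0, 90)
        group = [st.residue("A", 1).atom("OD1")]
        assert detect_hbonds(st, group) == 0

    def test_angle_boundary_included(self):
        st = carboxylate_probe(3.5, 100)
        group = [st.residue("A", 1).atom("OD1")]
        assert detect_hbonds(st, group) == 1

    def test_missing_antecedent_skipped_with_warning(self):
        st = micro_structure([
            ("A", 1, "ASP", [("OD1", "O", [0, 0, 0])]),   # no CG
            ("A", 2, "GLY", [("N", "N", [3.0, 0, 0]),
                             ("CA", "C", [3.0, 1.5, 0])]),
        ])
        group = [st.residue("A", 1).atom("OD1")]
        with pytest.warns(UserWarning):
            assert detect_hbonds(st, group) == 0


class TestElectrostaticEnergy:
    def _two_unit_charges(self, dist):
        st = micro_structure([
            ("A", 1, "UNK", [("X1", "C", [0, 0, 0])]),
            ("A", 2, "UNK", [("X2", "C", [dist, 0, 0])]),
        ])
        for atom in st.atoms():
            atom.partial_charge = 1.0
        return st

    def test_coulomb_closed_form(self):
        st = self._two_unit_charges(10.0)
        group = [st.residue("A", 1).atoms[0]]
        assert electrostatic_energy(st, group) == pytest.approx(
            COULOMB_K / 10.0)
        assert COULOMB_K / 10.0 == pytest.approx(33.2, abs=0.01)

    def test_cutoff_truncation(self):
        st = self._two_unit_charges(12.5)
        group = [st.residue("A", 1).atoms[0]]
        assert electrostatic_energy(st, group) == 0.0

    def test_symmetric_under_label_swap(self):
        st = self._two_unit_charges(7.0)
        g1 = [st.residue("A", 1).atoms[0]]
        g2 = [st.residue("A", 2).atoms[0]]
        assert electrostatic_energy(st, g1) == pytest.approx(
            electrostatic_energy(st, g2))

    def test_chargeless_environment(self):
        st = micro_structure([
            ("A", 1, "LYS", [("NZ", "N", [0, 0, 0])]),
            ("A", 2, "ALA", [("CB", "C", [5.0, 0, 0])]),
        ])
        group = [st.residue("A", 1).atom("NZ")]
        assert electrostatic_energy(st, group) == 0.0


class TestShrakeRupley:
    def test_isolated_sphere_analytic(self):
        st, _ = make_fixture("single_atom", {"element": "O"})
        asa, _ = asa_shrake_rupley(st)
        exact = 4 * np.pi * (1.52 + 1.4) ** 2
        assert asa[0] == pytest.approx(exact, rel=0.02)

    def test_fully_enclosed_atom_has_zero_asa(self):
        # central atom caged by a tight shell of neighbours
        shell = []
        k = 0
        for u in np.linspace(0, np.pi, 6):
            for v in np.linspace(0, 2 * np.pi, 12, endpoint=False):
                k += 1
                pos = 2.0 * np.array([np.sin(u) * np.cos(v),
                                      np.sin(u) * np.sin(v), np.cos(u)])
                shell.append(("A", k + 1, "UNK", [("C", "C", pos)]))
        st = micro_structure([("A", 1, "UNK", [("C", "C", [0, 0, 0])])]
                             + shell)
        asa, _ = asa_shrake_rupley(st)
        assert asa[0] == 0.0

    def test_two_sphere_spherical_cap_closed_form(self):
        d = 2.0
        st = micro_structure([
            ("A", 1, "UNK", [("C", "C", [0, 0, 0])]),
            ("A", 2, "UNK", [("C", "C", [d, 0, 0])]),
        ])
        asa, _ = asa_shrake_rupley(st)
        R = 1.7 + 1.4
        exact = 4 * np.pi * R ** 2 - 2 * np.pi * R * (R - d / 2)
        assert asa[0] == pytest.approx(exact, rel=0.03)
        assert asa[1] == pytest.approx(exact, rel=0.03)

    def test_far_fragments_are_additive(self):
        a = micro_structure([("A", 1, "UNK", [("C", "C", [0, 0, 0])]),
                             ("A", 2, "UNK", [("C", "C", [2.5, 0, 0])])])
        b = micro_structure([("B", 1, "UNK", [("C", "C", [80, 0, 0])])])
        both = micro_structure(
            [("A", 1, "UNK", [("C", "C", [0, 0, 0])]),
             ("A", 2, "UNK", [("C", "C", [2.5, 0, 0])]),
             ("B", 3, "UNK", [("C", "C", [80, 0, 0])])])
        asa_a, _ = asa_shrake_rupley(a)
        asa_b, _ = asa_shrake_rupley(b)
        asa_ab, _ = asa_shrake_rupley(both)
        assert asa_ab.sum() == pytest.approx(asa_a.sum() + asa_b.sum(),
                                             rel=1e-9)

    def test_point_refinement_reduces_sphere_error(self):
        st, _ = make_fixture("single_atom", {"element": "C"})
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        errors = []
        for n in (60, 240, 960):
            asa, _ = asa_shrake_rupley(st, n_points=n)
            errors.append(abs(asa[0] - exact))
        assert errors[2] <= errors[0]

    def test_sidechain_fraction_in_unit_interval(self):
        st, _ = make_fixture("peptide",
                             {"sequence": ["ASP", "LYS", "GLY"]})
        _, frac = asa_shrake_rupley(st)
        assert all(0.0 <= v <= 1.0 for v in frac.values())


class TestPredictPka:
    def test_zero_features_recover_intercepts(self):
        f0 = PkaFeatures(0, 0, 0, 0, 0)
        assert predict_pka(f0, "ASP", MODEL) == pytest.approx(1.62)
        assert predict_pka(f0, "LYS", MODEL) == pytest.approx(14.72)

    def test_zero_coefficients_return_model_pka(self):
        model = PkaModel(model_pka=dict(MODEL.model_pka),
                         coefficients={rt: (0, 0, 0, 0, 0, 0)
                                       for rt in MODEL.coefficients})
        f = PkaFeatures(3.1, 4.2, 2, -8.0, 0.3)
        for rt, expected in [("ASP", 3.8), ("GLU", 4.5), ("HIS", 6.5),
                             ("LYS", 10.5)]:
            assert predict_pka(f, rt, model) == pytest.approx(expected)

    @pytest.mark.parametrize("res_type", ["ASP", "GLU", "HIS", "LYS"])
    def test_exactly_linear_in_each_feature(self, res_type):
        base = PkaFeatures(2.0, 3.0, 1, -5.0, 0.4)
        c = MODEL.coefficients[res_type]
        for i, name in enumerate(
                ("depth_mc", "depth_polar_sc", "hb", "ee", "asa_sc")):
            bumped = PkaFeatures(**{**base.__dict__, name:
                                    getattr(base, name) + 1.0})
            slope = predict_pka(bumped, res_type, MODEL) - \
                predict_pka(base, res_type, MODEL)
            assert slope == pytest.approx(c[i + 1], abs=1e-9)

    def test_asa_slope_for_asp(self):
        base = PkaFeatures(0, 0, 0, 0, 0.0)
        up = PkaFeatures(0, 0, 0, 0, 1.0)
        assert predict_pka(up, "ASP", MODEL) - \
            predict_pka(base, "ASP", MODEL) == pytest.approx(-0.15,
                                                             abs=1e-9)


class TestEvaluateRmsd:
    def test_exact_match_is_zero(self):
        assert evaluate_rmsd([3.8, 4.5], [3.8, 4.5]) == 0.0

    def test_unit_errors(self):
        assert evaluate_rmsd([5.0, 3.0], [4.0, 4.0]) == pytest.approx(1.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert evaluate_rmsd(a, b) == pytest.approx(
            rmsd_loops(list(a), list(b)), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_rmsd([1.0], [1.0, 2.0])


def synthetic_training(model, n_per_type, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    training = []
    for rt in model.residue_types:
        c = model.coefficients[rt]
        for _ in range(n_per_type):
            v = rng.uniform([0, 0, 0, -20, 0], [10, 10, 4, 20, 1])
            f = PkaFeatures(*v)
            pka = model.model_pka[rt] + c[0] + float(
                np.dot(c[1:], f.as_vector()))
            training.append((f, rt, pka + rng.normal(0, noise)))
    return training


class TestFitCoefficients:
    def test_noiseless_recovery_to_1e6(self):
        training = synthetic_training(MODEL, 200)
        fit = fit_coefficients(training, MODEL.model_pka)
        for rt in MODEL.residue_types:
            np.testing.assert_allclose(fit.coefficients[rt],
                                       MODEL.coefficients[rt], atol=1e-6)

    def test_noise_bias_shrinks_with_n(self):
        errs = []
        for n in (50, 2000):
            fit = fit_coefficients(synthetic_training(MODEL, n,
                                                      noise=0.5, seed=4),
                                   MODEL.model_pka)
            errs.append(max(
                np.abs(np.array(fit.coefficients[rt])
                       - np.array(MODEL.coefficients[rt])).max()
                for rt in MODEL.residue_types))
        assert errs[1] < errs[0]

    def test_single_feature_slope_closed_form(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 40)
        y = 0.29 * x
        training = [(PkaFeatures(xi, 0, 0, 0, 0), "ASP",
                     MODEL.model_pka["ASP"] + yi)
                    for xi, yi in zip(x, y)]
        with pytest.warns(UserWarning):   # constant columns: rank deficient
            fit = fit_coefficients(training, MODEL.model_pka)
        xc = x - x.mean()
        slope = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
        assert fit.coefficients["ASP"][1] == pytest.approx(slope,
                                                           abs=1e-6)

    def test_too_few_examples_rejected(self):
        training = synthetic_training(MODEL, 3)
        with pytest.raises(ValueError):
            fit_coefficients(training, MODEL.model_pka)


class TestComputeFeatures:
    def test_exposed_asp_on_peptide(self):
        st, _ = make_fixture("peptide",
                             {"sequence": ["GLY", "ASP", "GLY"]})
        cfg = SolvationConfig(seed=1, n_iterations=4)
        depth = compute_depth(st, cfg)
        res = st.residue("A", 2)
        feats = compute_features(st, res, depth)
        assert feats.asa_sc > 0.5           # fully exposed side chain
        assert feats.depth_mc > 0
        assert feats.depth_polar_sc > 0
        assert feats.hb >= 0

    def test_unsupported_type_rejected(self):
        st, _ = make_fixture("peptide",
                             {"sequence": ["GLY", "SER", "GLY"]})
        cfg = SolvationConfig(seed=1, n_iterations=2)
        depth = compute_depth(st, cfg)
        with pytest.raises(ValueError):
            compute_features(st, st.residue("A", 2), depth)

    def test_deterministic_for_seed(self):
        st, _ = make_fixture("peptide",
                             {"sequence": ["GLY", "LYS", "GLY"]})
        cfg = SolvationConfig(seed=8, n_iterations=3)
        f1 = compute_features(st, st.residue("A", 2),
                              compute_depth(st, cfg))
        f2 = compute_features(st, st.residue("A", 2),
                              compute_depth(st, cfg))
        assert f1 == f2
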