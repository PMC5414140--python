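"""Generators: planted coordinates, covariance structure, benchmark harness."""

import numpy as np
import pytest

import depthqc as dq
from depthqc.errors import InvalidParameterError
from depthqc.simulate import (
    SimulationConfig,
    ar_covariance,
    evaluate_detection,
    make_example1,
    make_example2,
    mean_vectors,
    run_benchmark,
    simulate_expression,
)


class TestExample1:
    def test_planted_coordinates_verbatim(self):
        data = make_example1(seed=7)
        i3 = data.ids.index("g1_3")
        i8 = data.ids.index("g2_8")
        np.testing.assert_array_equal(data.matrix[i3], [-6, -6, -6])
        np.testing.assert_array_equal(data.matrix[i8], [6, 6, 6])
        assert data.truth_ids == {"g1_3", "g2_8"}

    def test_group_means_near_plus_minus_three(self):
        data = make_example1(seed=1)
        g1 = data.matrix[[i for i, s in enumerate(data.ids)
                          if s.startswith("g1") and s != "g1_3"]]
        g2 = data.matrix[[i for i, s in enumerate(data.ids)
                          if s.startswith("g2") and s != "g2_8"]]
        tol = 3.0 / np.sqrt(99)
        assert np.all(np.abs(g1.mean(axis=0) + 3.0) < 3 * tol)
        assert np.all(np.abs(g2.mean(axis=0) - 3.0) < 3 * tol)

    def test_same_seed_reproduces(self):
        a = make_example1(seed=42)
        b = make_example1(seed=42)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        assert a.ids == b.ids


class TestExample2:
    def test_planted_coordinates_and_truth(self):
        data = make_example2(seed=3)
        np.testing.assert_array_equal(
            data.matrix[data.ids.index("g1_73")], [3, 4, 25])
        np.testing.assert_array_equal(
            data.matrix[data.ids.index("g1_87")], [3, 10, 4])
        assert data.truth_ids == {"g1_73", "g1_87"}

    def test_exponential_components_nonnegative_with_expected_mean(self):
        data = make_example2(n_per_group=3000, seed=0)
        g1 = data.matrix[[i for i, s in enumerate(data.ids)
                          if s.startswith("g1")]]
        g2 = data.matrix[[i for i, s in enumerate(data.ids)
                          if s.startswith("g2")]]
        assert np.all(g1[:, 1] >= 0)          # skewed component of group 1
        assert np.all(g2[:, [0, 2]] >= 0)     # skewed components of group 2
        assert g1[:, 1].mean() == pytest.approx(4.0, rel=0.1)

    def test_rate_convention_flag(self):
        data = make_example2(n_per_group=3000, seed=0, exp_convention="rate")
        g1 = data.matrix[[i for i, s in enumerate(data.ids)
                          if s.startswith("g1") and s not in ("g1_73", "g1_87")]]
        assert g1[:, 1].mean() == pytest.approx(0.25, rel=0.1)


class TestARCovariance:
    def test_unit_diagonal_and_printed_formula(self):
        S = ar_covariance(50, 0.75, 0.01)
        np.testing.assert_allclose(np.diag(S), 1.0)
        assert S[0, 1] == pytest.approx(0.75 ** 0.01)
        assert S[3, 10] == pytest.approx(0.75 ** (0.01 * 7))

    def test_large_tau_approaches_identity(self):
        S = ar_covariance(20, 0.75, 200.0)
        off = S - np.eye(20)
        assert np.max(np.abs(off)) < 1e-20

    def test_positive_definite(self):
        S = ar_covariance(120, 0.75, 0.05)
        assert np.linalg.eigvalsh(S).min() > 0

    def test_empirical_covariance_converges(self):
        cfg = SimulationConfig(setting=1, d=40, n=4000, fc=0.0, tau=0.5,
                               n_outliers=0, seed=9)
        data = simulate_expression(cfg)
        emp = np.cov(data.matrix.T)
        S = ar_covariance(40, cfg.rho, cfg.tau)
        assert np.max(np.abs(emp - S)) < 0.15


class TestMeanVectors:
    def test_block_patterns(self):
        mv = mean_vectors(2, 0.75, 8, kappa_level=5.0)
        np.testing.assert_array_equal(mv["mu"], np.zeros(8))
        np.testing.assert_array_equal(mv["mu1"], np.full(8, 0.75))
        np.testing.assert_array_equal(mv["mu2"],
                                      [0.75] * 4 + [-0.75] * 4)
        np.testing.assert_array_equal(mv["mu3"],
                                      [0.75, 0.75, -0.75, -0.75] * 2)
        assert mv["mu2"].sum() == 0.0
        np.testing.assert_array_equal(mv["kappa"], np.full(8, 5.0))
        np.testing.assert_array_equal(mv["kappa1"], np.full(8, 5.75))

    def test_zero_fc_collapses_outlier_means(self):
        mv = mean_vectors(1, 0.0, 12)
        for key in ("mu1", "mu2", "mu3"):
            np.testing.assert_array_equal(mv[key], mv["mu"])

    def test_indivisible_d_rejected(self):
        with pytest.raises(InvalidParameterError):
            mean_vectors(1, 1.0, 10)


class TestSimulateExpression:
    def test_shapes_truth_and_group_levels(self):
        cfg = SimulationConfig(setting=2, d=100, n=30, fc=1.5, tau=0.1, seed=5)
        data = simulate_expression(cfg)
        assert data.matrix.shape == (60, 100)
        assert len(data.truth) == 6
        g2_reg = data.matrix[[i for i, s in enumerate(data.ids)
                              if s.startswith("g2") and s not in data.truth]]
        # correlated genes shrink the effective sample size; tolerance is wide
        assert g2_reg.mean() == pytest.approx(5.0, abs=0.6)
        g1_reg = data.matrix[[i for i, s in enumerate(data.ids)
                              if s.startswith("g1") and s not in data.truth]]
        assert g1_reg.mean() == pytest.approx(0.0, abs=0.6)

    def test_determinism(self):
        cfg = SimulationConfig(setting=1, d=48, n=12, fc=1.0, tau=0.1, seed=2)
        a = simulate_expression(cfg)
        b = simulate_expression(cfg)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        assert a.truth == b.truth


class TestEvaluateDetection:
    def test_perfect_and_empty_flagging(self):
        assert evaluate_detection({"a", "b"}, {"a", "b"}, 10) == (1.0, 1.0)
        assert evaluate_detection(set(), {"a"}, 10) == (0.0, 1.0)

    def test_mixed_flagging_arithmetic(self):
        sens, spec = evaluate_detection({"a", "x"}, {"a", "b", "c"}, 100)
        assert sens == pytest.approx(1 / 3)
        assert spec == pytest.approx(1.0 - 1.0 / 97.0)

    def test_empty_truth_reports_missing_sensitivity(self):
        sens, spec = evaluate_detection({"a"}, set(), 10)
        assert sens is None
        assert spec == pytest.approx(0.9)


class TestRunBenchmark:
    def test_single_rep_deterministic_summary(self):
        cfgs = [SimulationConfig(setting=1, d=80, n=24, fc=3.0, tau=0.1)]
        a = run_benchmark(cfgs, n_reps=2, methods=("1D",), seed=4)
        b = run_benchmark(cfgs, n_reps=2, methods=("1D",), seed=4)
        assert a.equals(b)
        assert set(a["method"]) == {"1D"}
        assert ((a["sensitivity"] >= 0) & (a["sensitivity"] <= 1)).all()

    def test_recoverability_grows_with_fc(self):
        base = dict(setting=1, d=80, n=30, tau=0.1)
        cfgs = [SimulationConfig(fc=0.5, **base),
                SimulationConfig(fc=6.0, **base)]
        tab = run_benchmark(cfgs, n_reps=4, methods=("1D",), seed=8)
        lo = tab[tab.fc == 0.5].sensitivity.iloc[0]
        hi = tab[tab.fc == 6.0].sensitivity.iloc[0]
        assert hi >= lo
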