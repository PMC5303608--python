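import numpy as np
import pytest

from grncascade import ExpressionMatrix, fit_mlr, infer_network
from grncascade.exceptions import (
    CollinearDesignError,
    OverdefinedModelError,
    ValidationError,
)

from conftest import make_expression
from oracles import ols_normal_equations


class TestFitMlr:
    def test_exact_linear_dependence_recovered(self, rng):
        x1 = rng.normal(size=40)
        x2 = rng.normal(size=40)
        y = 2.0 * x1
        fit = fit_mlr(y, np.column_stack([x1, x2]), ["x1", "x2"])
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-10)
        assert fit.p_values[0] < 1e-12

    def test_frozen_integer_instance_matches_normal_equations(self):
        # 6 observations, 2 predictors, hand-chosen integers.
        X = np.array([[1, 2], [2, 1], [3, 5], [4, 2], [5, 7], [6, 1]], dtype=float)
        y = np.array([3.0, 4.0, 9.0, 8.0, 14.0, 11.0])
        params, se, t_stats, p_values, df = ols_normal_equations(y, X)
        fit = fit_mlr(y, X, ["x1", "x2"])
        assert fit.intercept == pytest.approx(params[0], abs=1e-10)
        np.testing.assert_allclose(fit.coefficients, params[1:], atol=1e-10)
        np.testing.assert_allclose(fit.standard_errors, se[1:], atol=1e-10)
        np.testing.assert_allclose(fit.p_values, p_values[1:], atol=1e-10)
        assert fit.residual_df == df == 3

    def test_random_instances_match_normal_equations_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 51))
            k = int(rng.integers(1, 6))
            X = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            params, se, t_stats, p_values, _ = ols_normal_equations(y, X)
            fit = fit_mlr(y, X, [f"x{j}" for j in range(k)])
            np.testing.assert_allclose(
                np.r_[fit.intercept, fit.coefficients], params, atol=1e-8
            )
            np.testing.assert_allclose(fit.standard_errors, se[1:], atol=1e-8)
            np.testing.assert_allclose(fit.t_statistics, t_stats[1:], atol=1e-6)
            np.testing.assert_allclose(fit.p_values, p_values[1:], atol=1e-8)

    def test_duplicated_predictor_column_rejected(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(CollinearDesignError, match="not invertible"):
            fit_mlr(rng.normal(size=20), np.column_stack([x, x]), ["a", "b"])

    def test_overdefined_model_rejected(self, rng):
        X = rng.normal(size=(4, 3))
        with pytest.raises(OverdefinedModelError, match="more samples"):
            fit_mlr(rng.normal(size=4), X, ["a", "b", "c"])

    def test_residual_orthogonality(self, rng):
        for _ in range(20):
            n, k = int(rng.integers(10, 60)), int(rng.integers(1, 6))
            X = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            fit = fit_mlr(y, X, [f"x{j}" for j in range(k)])
            resid = y - fit.intercept - X @ fit.coefficients
            Xc = np.column_stack([np.ones(n), X])
            assert np.max(np.abs(Xc.T @ resid)) < 1e-8

    def test_scale_equivariance(self, rng):
        n, k = 30, 3
        X = rng.normal(size=(n, k))
        y = X @ np.array([1.0, -0.5, 0.3]) + rng.normal(size=n)
        base = fit_mlr(y, X, ["a", "b", "c"])
        for c in (2.0, -0.25, 1e3):
            Xs = X.copy()
            Xs[:, 1] *= c
            scaled = fit_mlr(y, Xs, ["a", "b", "c"])
            assert scaled.coefficients[1] == pytest.approx(
                base.coefficients[1] / c, rel=1e-8
            )
            # two-sided inference: a negative scale flips t's sign only
            assert abs(scaled.t_statistics[1]) == pytest.approx(
                abs(base.t_statistics[1]), rel=1e-8
            )
            assert scaled.p_values[1] == pytest.approx(base.p_values[1], abs=1e-8)

    def test_coefficient_rmse_shrinks_with_sample_size(self):
        beta = np.array([1.0, -0.8, 0.6])
        rmse_by_n = []
        for n in (50, 200, 1000):
            errs = []
            for seed in range(20):
                gen = np.random.default_rng(1000 + seed)
                X = gen.normal(size=(n, 3))
                y = X @ beta + gen.normal(scale=1.0, size=n)
                fit = fit_mlr(y, X, ["a", "b", "c"])
                errs.append(np.sqrt(np.mean((fit.coefficients - beta) ** 2)))
            rmse_by_n.append(np.mean(errs))
        assert rmse_by_n[0] >= rmse_by_n[1] >= rmse_by_n[2]

    def test_power_at_five_sigma_effect(self):
        # |beta| = 5 * noise_sd / sqrt(n) should be detected nearly always.
        n, sd = 100, 1.0
        beta = 5.0 * sd / np.sqrt(n)
        hits = 0
        for seed in range(200):
            gen = np.random.default_rng(2000 + seed)
            X = gen.normal(size=(n, 2))
            y = beta * X[:, 0] + gen.normal(scale=sd, size=n)
            fit = fit_mlr(y, X, ["a", "b"])
            hits += fit.p_values[0] < 0.05
        assert hits / 200 >= 0.95


class TestInferNetwork:
    def test_scored_edges_enumerate_all_ordered_pairs(self, rng):
        expr = make_expression(rng.normal(size=(6, 40)))
        preds = infer_network(expr)
        assert len(preds.scored_edges) == 6 * 5
        assert len({(a, b) for a, b, _s, _p in preds.scored_edges}) == 30

    def test_alpha_threshold_is_strict(self, rng):
        expr = make_expression(rng.normal(size=(5, 60)))
        preds = infer_network(expr, alpha=0.05)
        p_of = {(a, b): p for a, b, _s, p in preds.scored_edges}
        for pair, p in p_of.items():
            assert (pair in preds.called_edges) == (p < 0.05)

    def test_too_few_observations_points_to_subnetworks(self, rng):
        expr = make_expression(rng.normal(size=(10, 8)))
        with pytest.raises(OverdefinedModelError, match="subnetwork"):
            infer_network(expr)

    def test_constant_gene_excluded_with_warning(self, rng):
        values = rng.normal(size=(5, 50))
        values[2] = 3.14  # constant expression
        expr = make_expression(values)
        preds = infer_network(expr)
        assert any("g3" in w for w in preds.warnings)
        assert len(preds.scored_edges) == 20  # pair universe unchanged
        p_of = {(a, b): p for a, b, _s, p in preds.scored_edges}
        assert all(p_of[(a, "g3")] == 1.0 for a in ("g1", "g2", "g4", "g5"))

    def test_standardization_leaves_p_values_unchanged(self, rng):
        expr = make_expression(rng.normal(size=(5, 80)) * 7.0 + 3.0)
        raw = infer_network(expr, standardize=False)
        std = infer_network(expr, standardize=True)
        p_raw = {(a, b): p for a, b, _s, p in raw.scored_edges}
        p_std = {(a, b): p for a, b, _s, p in std.scored_edges}
        for pair in p_raw:
            assert p_raw[pair] == pytest.approx(p_std[pair], abs=1e-8)

    def test_regulator_filter_limits_predictors(self, rng):
        expr = make_expression(rng.normal(size=(5, 60)))
        preds = infer_network(expr, regulators=["g1", "g2"])
        nontrivial = {
            (a, b) for a, b, _s, p in preds.scored_edges if p < 1.0
        }
        assert all(a in ("g1", "g2") for a, _b in nontrivial)

    def test_bonferroni_never_calls_more_edges(self, rng):
        expr = make_expression(rng.normal(size=(6, 80)))
        raw = infer_network(expr)
        bonf = infer_network(expr, correction="bonferroni")
        assert bonf.called_edges <= raw.called_edges

    def test_bad_alpha_rejected(self, rng):
        expr = make_expression(rng.normal(size=(3, 20)))
        with pytest.raises(ValidationError):
            infer_network(expr, alpha=1.5)
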