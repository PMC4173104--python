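import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from centerbench.propensity import (
    fit_ps_multinomial,
    fit_ps_per_center,
    multinomial_score,
    ps_overlap_report,
    stabilize_weights,
)
from centerbench.registry_io import registry_from_frame


def _no_covariate_registry(seed=0, sizes=(150, 100, 50)):
    rng = np.random.default_rng(seed)
    centers = np.repeat([f"c{i}" for i in range(len(sizes))], sizes)
    df = pd.DataFrame({"outcome": rng.integers(0, 2, sum(sizes)),
                       "center": centers})
    return registry_from_frame(df)


def _confounded_registry(seed, n=5000, m=3, gamma=None, delta=None):
    """Draw (L, C) from a known multinomial assignment model."""
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((n, 2))
    gamma = np.array([0.0, 0.3, -0.2]) if gamma is None else gamma
    delta = (
        np.array([[0.0, 0.0], [0.5, -0.3], [-0.4, 0.2]])
        if delta is None
        else delta
    )
    eta = gamma[None, :] + L @ delta.T
    pr = np.exp(eta - eta.max(axis=1, keepdims=True))
    pr /= pr.sum(axis=1, keepdims=True)
    C = (rng.random(n)[:, None] > np.cumsum(pr, axis=1)).sum(axis=1)
    df = pd.DataFrame(
        {
            "outcome": rng.integers(0, 2, n),
            "center": [f"c{c}" for c in C],
            "x1": L[:, 0],
            "x2": L[:, 1],
        }
    ).sort_values("center", kind="stable").reset_index(drop=True)
    return registry_from_frame(df, covariates=["x1", "x2"]), gamma, delta


class TestMultinomial:
    def test_intercept_only_probabilities_are_center_shares(self):
        reg = _no_covariate_registry()
        fit = fit_ps_multinomial(reg)
        shares = reg.center_sizes / reg.n
        assert np.allclose(fit.prob_matrix, shares[None, :], atol=1e-8)

    def test_rows_sum_to_one(self):
        reg, _, _ = _confounded_registry(seed=1, n=800)
        fit = fit_ps_multinomial(reg)
        assert np.allclose(fit.prob_matrix.sum(axis=1), 1.0, atol=1e-10)

    def test_score_equations_satisfied(self):
        reg, _, _ = _confounded_registry(seed=2, n=1500)
        fit = fit_ps_multinomial(reg)
        ref = fit.centers.index(fit.reference_center)
        X1 = np.hstack([np.ones((reg.n, 1)), reg.X])
        score = multinomial_score(fit.coefficients, X1, reg.center_codes, ref)
        assert np.max(np.abs(score)) < 1e-6

    def test_recovers_known_assignment_model(self):
        reg, gamma, delta = _confounded_registry(seed=3, n=5000)
        fit = fit_ps_multinomial(reg)
        # asymptotic SEs from the numerically differentiated mean score
        ref = fit.centers.index(fit.reference_center)
        free = [c for c in range(3) if c != ref]
        X1 = np.hstack([np.ones((reg.n, 1)), reg.X])
        theta = np.concatenate([fit.coefficients[c] for c in free])

        def score_of(th):
            coef = np.zeros((3, 3))
            for b, c in enumerate(free):
                coef[c] = th[b * 3:(b + 1) * 3]
            return multinomial_score(coef, X1, reg.center_codes, ref)

        d = len(theta)
        J = np.zeros((d, d))
        for j in range(d):
            h = 1e-6
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            J[:, j] = (score_of(tp) - score_of(tm)) / (2 * h)
        cov = np.linalg.inv(-J) / reg.n
        se = np.sqrt(np.diag(cov))
        truth = np.concatenate(
            [np.r_[gamma[c], delta[c]] for c in free]
        )
        assert np.all(np.abs(theta - truth) < 3 * se)


class TestPerCenter:
    def test_intercept_only_matches_center_shares(self):
        reg = _no_covariate_registry(seed=4)
        fit = fit_ps_per_center(reg)
        shares = reg.center_sizes / reg.n
        assert np.allclose(fit.prob_matrix, shares[None, :], atol=1e-8)

    def test_rows_sum_to_one_after_normalization(self):
        reg, _, _ = _confounded_registry(seed=5, n=600)
        fit = fit_ps_per_center(reg)
        assert np.allclose(fit.prob_matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_close_to_multinomial_under_weak_confounding(self):
        delta = 0.1 * np.array([[0.0, 0.0], [1.0, -0.6], [-0.8, 0.4]])
        reg, _, _ = _confounded_registry(seed=6, n=5000, delta=delta)
        a = fit_ps_multinomial(reg)
        b = fit_ps_per_center(reg)
        assert np.max(np.abs(a.prob_matrix - b.prob_matrix)) < 0.02

    def test_two_center_forms_coincide(self):
        rng = np.random.default_rng(7)
        n = 400
        L = rng.standard_normal(n)
        C = (rng.random(n) < expit(0.4 * L)).astype(int)
        df = pd.DataFrame(
            {"outcome": rng.integers(0, 2, n),
             "center": [f"c{c}" for c in C], "x1": L}
        )
        reg = registry_from_frame(df, covariates=["x1"])
        a = fit_ps_multinomial(reg)
        b = fit_ps_per_center(reg)
        assert np.max(np.abs(a.prob_matrix - b.prob_matrix)) < 1e-6


class TestStabilizedWeights:
    def test_no_covariates_gives_unit_weights(self):
        reg = _no_covariate_registry(seed=8)
        fit = fit_ps_multinomial(reg)
        sw = stabilize_weights(fit, reg)
        assert np.allclose(sw.weights, 1.0, atol=1e-10)

    def test_mean_weight_near_one_within_center(self):
        reg, _, _ = _confounded_registry(seed=9, n=10_000)
        fit = fit_ps_multinomial(reg)
        sw = stabilize_weights(fit, reg)
        for c in range(reg.m):
            w = sw.weights[reg.center_codes == c]
            mc_se = w.std(ddof=1) / np.sqrt(len(w))
            assert abs(w.mean() - 1.0) < 3 * mc_se + 1e-3

    def test_extreme_weight_reported_not_truncated(self):
        reg = _no_covariate_registry(seed=10, sizes=(99, 1))
        fit = fit_ps_multinomial(reg)
        # overwrite one fitted propensity with a pathologically small value
        fit.prob_matrix[-1, 1] = 1e-6
        sw = stabilize_weights(fit, reg)
        assert sw.weights[-1] == pytest.approx(0.01 / 1e-6)
        assert (sw.extreme["record"] == reg.n - 1).any()

    def test_stabilization_preserves_within_center_ranking(self):
        reg, _, _ = _confounded_registry(seed=11, n=2000)
        fit = fit_ps_multinomial(reg)
        sw = stabilize_weights(fit, reg)
        g_own = fit.prob_matrix[np.arange(reg.n), reg.center_codes]
        for c in range(reg.m):
            sel = reg.center_codes == c
            raw_rank = np.argsort(1.0 / g_own[sel])
            stab_rank = np.argsort(sw.weights[sel])
            assert np.array_equal(raw_rank, stab_rank)


class TestOverlapReport:
    def test_row_count_is_m(self):
        reg, _, _ = _confounded_registry(seed=12, n=600)
        fit = fit_ps_multinomial(reg)
        report = ps_overlap_report(fit, reg)
        assert len(report) == reg.m

    def test_uniform_ps_flags_nothing(self):
        reg = _no_covariate_registry(seed=13)
        fit = fit_ps_multinomial(reg)
        report = ps_overlap_report(fit, reg)
        assert not report["flagged"].any()

    def test_divergent_case_mix_center_flagged(self):
        # one center treats only very old patients while age drives assignment
        rng = np.random.default_rng(14)
        n_major, n_minor = 2000, 25
        age_major = rng.standard_normal(n_major)
        age_minor = rng.normal(3.5, 0.2, n_minor)
        df = pd.DataFrame(
            {
                "outcome": rng.integers(0, 2, n_major + n_minor),
                "center": ["big"] * n_major + ["old"] * n_minor,
                "age": np.r_[age_major, age_minor],
            }
        )
        reg = registry_from_frame(df, covariates=["age"])
        fit = fit_ps_per_center(reg)
        report = ps_overlap_report(fit, reg).set_index("center")
        # the big center's own patients include some with tiny probability
        # of belonging to it once age is extreme
        assert report.loc["big", "flagged"] or report.loc["old", "flagged"]
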