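import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from centerbench.outcome_models import (
    RankDeficiencyError,
    fit_fe_logistic,
    fit_me_clustered,
    fit_me_normal,
    predict_risk,
)
from centerbench.registry_io import registry_from_frame

from conftest import make_registry

LEAN = {"chains": 2, "warmup": 400, "draws": 400, "rhat_threshold": 1.2}


def _single_center(events, n):
    df = pd.DataFrame({"outcome": [1] * events + [0] * (n - events),
                       "center": ["a"] * n})
    return registry_from_frame(df)


class TestFixedEffects:
    def test_intercept_only_ml_is_empirical_logit(self):
        fit = fit_fe_logistic(_single_center(3, 10))
        assert fit.psi[0] == pytest.approx(logit(0.3), abs=1e-10)

    @pytest.mark.parametrize("events,n", [(0, 10), (1, 7), (5, 12), (12, 12), (2, 50)])
    def test_intercept_only_firth_closed_form(self, events, n):
        fit = fit_fe_logistic(_single_center(events, n), firth=True)
        assert fit.psi[0] == pytest.approx(logit((events + 0.5) / (n + 1)), abs=1e-8)

    def test_zero_events_ml_flagged_divergent(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_fe_logistic(_single_center(0, 10))
        assert not fit.converged

    def test_separation_ml_flagged_firth_finite(self):
        df = pd.DataFrame(
            {"outcome": [1] * 5 + [0] * 5, "center": ["a"] * 10,
             "x1": [1.0] * 5 + [0.0] * 5}
        )
        reg = registry_from_frame(df, covariates=["x1"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ml = fit_fe_logistic(reg)
        assert not ml.converged and "x1" in ml.diverging
        fi = fit_fe_logistic(reg, firth=True)
        assert fi.converged
        assert np.all(np.isfinite(fi.beta)) and np.all(np.isfinite(fi.psi))
        assert fi.grad_norm < 1e-8

    def test_unit_weights_equal_unweighted(self):
        reg, _ = make_registry(seed=3, m=3, n_c=80)
        a = fit_fe_logistic(reg, firth=True)
        b = fit_fe_logistic(reg, firth=True, weights=np.ones(reg.n))
        assert np.allclose(a.params(), b.params(), atol=1e-8)

    def test_matches_statsmodels_glm(self):
        # independent route: same likelihood maximized by statsmodels
        import statsmodels.api as sm

        reg, _ = make_registry(seed=7, m=4, n_c=150, beta=(0.6, -0.3))
        fit = fit_fe_logistic(reg)
        onehot = pd.get_dummies(reg.data["center"]).to_numpy(dtype=float)
        Z = np.hstack([reg.X, onehot])
        res = sm.GLM(reg.y, Z, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.params(), res.params, atol=1e-6)

    def test_firth_ml_gap_shrinks_with_large_centers(self):
        reg, _ = make_registry(seed=11, m=4, n_c=500)
        ml = fit_fe_logistic(reg)
        fi = fit_fe_logistic(reg, firth=True)
        assert np.max(np.abs(fi.psi - ml.psi)) < 0.05

    def test_rank_deficiency_names_aliased_column(self):
        df = pd.DataFrame(
            {
                "outcome": [0, 1, 0, 1, 1, 0],
                "center": list("aaabbb"),
                "x1": [1.0, 2, 3, 4, 5, 6],
                "x2": [2.0, 4, 6, 8, 10, 12],   # aliased: 2 * x1
            }
        )
        reg = registry_from_frame(df, covariates=["x1", "x2"])
        with pytest.raises(RankDeficiencyError, match="x"):
            fit_fe_logistic(reg)


class TestPredictRisk:
    def test_zero_linear_predictor_is_half(self):
        reg, _ = make_registry(seed=1, m=2, n_c=20)
        fit = fit_fe_logistic(reg, firth=True)
        fit.beta[:] = 0.0
        fit.psi[:] = 0.0
        assert predict_risk(fit, [0.0], "c00") == pytest.approx(0.5)

    def test_saturated_fit_reproduces_stratum_risk(self, table1_registry):
        fit = fit_fe_logistic(table1_registry, interactions=["L"])
        assert predict_risk(fit, [1.0], "3") == pytest.approx(0.12, abs=1e-6)
        assert predict_risk(fit, [0.0], "1") == pytest.approx(0.01, abs=1e-6)

    def test_monotone_in_center_effect(self):
        reg, _ = make_registry(seed=2, m=3, n_c=30)
        fit = fit_fe_logistic(reg, firth=True)
        base = predict_risk(fit, [0.3], "c01")
        fit.psi[1] += 1.0
        assert predict_risk(fit, [0.3], "c01") > base

    def test_unknown_center_raises(self):
        reg, _ = make_registry(seed=2, m=3, n_c=30)
        fit = fit_fe_logistic(reg, firth=True)
        with pytest.raises(KeyError):
            predict_risk(fit, [0.0], "nope")


class TestMixedEffects:
    def test_homogeneous_centers_concentrate_sigma_near_zero(self):
        reg, _ = make_registry(seed=21, m=30, n_c=200, beta=(0.5,),
                               psi=np.full(30, -1.3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_me_normal(reg, mcmc={**LEAN, "seed": 1})
        assert np.median(fit.stacked("sigma_psi")) < 0.1

    def test_recovers_heterogeneous_center_effects(self):
        reg, psi = make_registry(seed=22, m=50, n_c=200, beta=(0.5,), psi_sd=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_me_normal(reg, mcmc={**LEAN, "seed": 2})
        r = np.corrcoef(fit.posterior_mean_psi(), psi)[0, 1]
        assert r > 0.8

    def test_small_center_shrinks_toward_grand_mean(self):
        rng = np.random.default_rng(5)
        sizes = [200] * 9 + [10]
        psi = np.concatenate([np.full(9, -1.2), [-2.6]])  # deviant small center
        rows = []
        for c, (nc, s) in enumerate(zip(sizes, psi)):
            y = (rng.random(nc) < expit(s)).astype(int)
            rows.append(pd.DataFrame({"outcome": y, "center": f"c{c:02d}"}))
        reg = registry_from_frame(pd.concat(rows, ignore_index=True))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            me = fit_me_normal(reg, mcmc={**LEAN, "seed": 3})
            fe = fit_fe_logistic(reg, firth=True)
        pm = fit_posterior = me.posterior_mean_psi()
        grand = me.stacked("mu_psi").mean()
        # the small deviant center is pulled toward the population mean
        assert abs(pm[-1] - fe.psi[-1]) > 0.05
        assert abs(pm[-1] - grand) < abs(fe.psi[-1] - grand)

    def test_shrinkage_reduces_effect_variance_across_replicates(self):
        wins = 0
        reps = 10
        for s in range(reps):
            reg, _ = make_registry(seed=100 + s, m=20, n_c=40, psi_sd=0.5)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                me = fit_me_normal(
                    reg, mcmc={"chains": 2, "warmup": 250, "draws": 250,
                               "rhat_threshold": 2.0, "seed": s}
                )
                fe = fit_fe_logistic(reg, firth=True)
            wins += me.posterior_mean_psi().var() <= fe.psi.var()
        assert wins >= 0.9 * reps

    def test_too_few_centers_rejected(self):
        reg, _ = make_registry(seed=1, m=2, n_c=50)
        with pytest.raises(ValueError, match="m >= 3"):
            fit_me_normal(reg)


class TestClusteredMixedEffects:
    def test_k1_matches_plain_normal_model(self):
        reg, _ = make_registry(seed=31, m=12, n_c=80, psi_sd=0.4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_me_normal(reg, mcmc={**LEAN, "seed": 4})
            b = fit_me_clustered(reg, K=1, mcmc={**LEAN, "seed": 4})
        assert np.allclose(a.posterior_mean_psi(), b.posterior_mean_psi(), atol=0.08)

    def test_two_component_truth_recovered(self):
        rng = np.random.default_rng(9)
        m = 40
        comp = rng.random(m) < 0.5
        psi = np.where(comp, 1.0, -1.0) + 0.1 * rng.standard_normal(m)
        reg, _ = make_registry(seed=32, m=m, n_c=150, beta=(0.0,), psi=psi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_me_clustered(reg, K=2, mcmc={**LEAN, "seed": 5})
        z = fit.stacked("z")
        zmode = np.array([np.bincount(z[:, c], minlength=2).argmax()
                          for c in range(m)])
        acc = max(np.mean(zmode == comp), np.mean(zmode == ~comp))
        assert acc > 0.9

    def test_mixture_weights_stay_on_simplex(self):
        reg, _ = make_registry(seed=33, m=10, n_c=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_me_clustered(
                reg, K=3,
                mcmc={"chains": 1, "warmup": 100, "draws": 100,
                      "rhat_threshold": 10.0, "seed": 6},
            )
        p = fit.stacked("p_k")
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_k_rejected(self):
        reg, _ = make_registry(seed=1, m=5, n_c=30)
        with pytest.raises(ValueError):
            fit_me_clustered(reg, K=5)
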