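"""Direct and indirect standardization of center performance.

Direct standardization reports, for every center c, the potential full
population risk

    E{Y(c)} = E{ E(Y | L, C=c) },   estimated by
    (1/n) sum_i expit(L_i' beta + psi_c),

i.e. the event risk the whole pooled population would experience under
center c's care level.  Indirect standardization reports the SMR (ratio of
a center's risk on its own patients to the risk those patients would face
under the average care level across centers) and the excess risk
(difference form).  The doubly robust variant refits the outcome model by
stabilized inverse-propensity-weighted regression before standardizing,
which keeps the estimator consistent when either the outcome model or the
propensity model (but not necessarily both) is correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .outcome_models import FEFit, MEDraws, fit_fe_logistic, _split_design
from .propensity import (
    PSFit,
    multinomial_prob_matrix,
    stabilize_weights,
)
from .registry_io import Registry, StratumTable

__all__ = [
    "StandardizedEstimate",
    "IndirectEstimate",
    "direct_risk",
    "dr_risk",
    "indirect_standardize",
    "stratum_oracle",
    "estimates_frame",
]


@dataclass
class StandardizedEstimate:
    """Per-center potential full-population risk with its standard error."""

    center_id: str
    estimate: float
    sd: float
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.estimate <= 1.0:
            raise ValueError(f"estimate {self.estimate} outside [0,1]")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass
class IndirectEstimate:
    """Per-center SMR (ratio) and excess risk (difference)."""

    center_id: str
    smr: float
    excess_risk: float


def estimates_frame(estimates: list[StandardizedEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "center": [e.center_id for e in estimates],
            "estimate": [e.estimate for e in estimates],
            "sd": [e.sd for e in estimates],
            "method": [e.method for e in estimates],
        }
    )


def _fe_risk_matrix(fit: FEFit, registry: Registry) -> np.ndarray:
    """n x m matrix of f(L_i, c) under the fitted fixed-effects model."""
    Xp, Xi = _split_design(registry, fit.covariate_cols, fit.interaction_cols)
    eta0 = Xp @ fit.beta if fit.beta.size else np.zeros(registry.n)
    out = np.empty((registry.n, fit.m))
    for c in range(fit.m):
        eta = eta0 + fit.psi[c]
        for j in range(len(fit.interaction_cols)):
            eta = eta + Xi[:, j] * fit.gamma[j, c]
        out[:, c] = expit(eta)
    return out


def _fe_direct_gradients(fit: FEFit, registry: Registry, F: np.ndarray) -> np.ndarray:
    """Gradient of (1/n) sum_i f(L_i, c) w.r.t. (beta, gamma, psi), per center."""
    Xp, Xi = _split_design(registry, fit.covariate_cols, fit.interaction_cols)
    n, m = registry.n, fit.m
    p0, p1 = Xp.shape[1], Xi.shape[1]
    grads = np.zeros((m, p0 + p1 * m + m))
    for c in range(m):
        v = F[:, c] * (1 - F[:, c])
        if p0:
            grads[c, :p0] = Xp.T @ v / n
        for j in range(p1):
            grads[c, p0 + j * m + c] = float(Xi[:, j] @ v) / n
        grads[c, p0 + p1 * m + c] = float(v.mean())
    return grads


def _check_schema(fit, registry: Registry) -> None:
    if isinstance(fit, FEFit):
        want = set(fit.covariate_cols) | set(fit.interaction_cols)
    else:
        want = set(fit.covariate_cols)
    if not want <= set(registry.covariate_cols):
        raise ValueError(
            f"fit covariates {sorted(want)} not all present in registry "
            f"({sorted(registry.covariate_cols)})"
        )
    if list(fit.centers) != list(registry.centers):
        raise ValueError("fit and registry disagree on the center index")


def _me_eta0(draws: MEDraws, registry: Registry, max_draws: int) -> tuple[np.ndarray, np.ndarray]:
    B = draws.stacked("beta")
    Psi = draws.stacked("psi")
    S = B.shape[0]
    if S > max_draws:
        idx = np.linspace(0, S - 1, max_draws).astype(int)
        B, Psi = B[idx], Psi[idx]
    X = registry.data[draws.covariate_cols].to_numpy(dtype=float) if draws.covariate_cols else np.empty((registry.n, 0))
    eta0 = X @ B.T if B.shape[1] else np.zeros((registry.n, B.shape[0]))
    return eta0, Psi


def direct_risk(
    fit: FEFit | MEDraws, registry: Registry, max_draws: int = 1000
) -> list[StandardizedEstimate]:
    """Directly standardized potential full-population risk per center.

    For a fixed-effects fit the plug-in average of predicted risks over all
    n patients is reported with a delta-method standard error (gradient of
    the plug-in functional times the inverse observed information).  For
    mixed-effects draws the functional is evaluated draw by draw and the
    posterior mean and sd are reported.
    """
    _check_schema(fit, registry)
    if isinstance(fit, FEFit):
        F = _fe_risk_matrix(fit, registry)
        est = F.mean(axis=0)
        grads = _fe_direct_gradients(fit, registry, F)
        Iinv_g = np.linalg.solve(fit.information, grads.T)
        var = np.einsum("cd,dc->c", grads, Iinv_g)
        sd = np.sqrt(np.clip(var, 0, None))
        method = "fe_firth" if fit.firth else "fe_ml"
        if fit.weights_used is not None:
            method = "dr_ps"
        return [
            StandardizedEstimate(c, float(est[i]), float(sd[i]), method)
            for i, c in enumerate(fit.centers)
        ]
    # mixed-effects draws: evaluate the functional per draw
    eta0, Psi = _me_eta0(fit, registry, max_draws)
    method = "me_clustered" if fit.K > 1 else "me_normal"
    out = []
    for c, name in enumerate(fit.centers):
        vals = expit(eta0 + Psi[:, c][None, :]).mean(axis=0)
        out.append(
            StandardizedEstimate(name, float(vals.mean()), float(vals.std(ddof=1)), method)
        )
    return out


def indirect_standardize(
    fit: FEFit | MEDraws, registry: Registry, max_draws: int = 1000
) -> list[IndirectEstimate]:
    """Indirectly standardized SMR and excess risk per center.

    The numerator is the average predicted risk of center c's own patients
    under center c; the denominator averages, unweighted over all m centers
    c*, the predicted risk of those same patients under c*.
    """
    _check_schema(fit, registry)
    codes = registry.center_codes
    if isinstance(fit, FEFit):
        F = _fe_risk_matrix(fit, registry)
        out = []
        for c, name in enumerate(fit.centers):
            own = codes == c
            num = float(F[own, c].mean())
            den = float(F[own, :].mean(axis=0).mean())
            if den == 0:
                raise ZeroDivisionError(f"zero expected risk for center {name!r}")
            out.append(IndirectEstimate(name, num / den, num - den))
        return out
    eta0, Psi = _me_eta0(fit, registry, max_draws)
    out = []
    for c, name in enumerate(fit.centers):
        own = codes == c
        num_s = expit(eta0[own] + Psi[:, c][None, :]).mean(axis=0)
        den_s = np.mean(
            [expit(eta0[own] + Psi[:, c2][None, :]).mean(axis=0) for c2 in range(fit.m)],
            axis=0,
        )
        smr_s = num_s / den_s
        out.append(IndirectEstimate(name, float(smr_s.mean()), float((num_s - den_s).mean())))
    return out


# ---------------------------------------------------------------------------
# doubly robust propensity-weighted standardization
# ---------------------------------------------------------------------------

def _firth_score_offset(fit: FEFit, registry: Registry, weights: np.ndarray) -> np.ndarray:
    """Known per-center offset of the weighted score at a Firth optimum.

    At a Jeffreys-penalized optimum the plain weighted score equals minus the
    penalty term  sum_i h_i (1/2 - p_i) z_i ; the center-indicator components
    of that term quantify exactly how far the augmented and plug-in forms of
    the standardized risk may drift apart.
    """
    from .outcome_models import build_design

    Z, _, _, _ = build_design(registry, fit.interaction_cols)
    p = fit.predicted_risk(registry)
    W = weights * p * (1 - p)
    I = Z.T @ (Z * W[:, None])
    ZI = np.linalg.solve(I, Z.T)
    h = W * np.einsum("ij,ji->i", Z, ZI)
    pen = Z.T @ (h * (0.5 - p))
    return pen[-registry.m:]


def dr_risk(
    registry: Registry,
    psfit: PSFit,
    firth: bool = True,
    interactions: list[str] | None = None,
    identity_tol: float = 1e-6,
    compute_sd: bool = True,
) -> list[StandardizedEstimate]:
    """Doubly robust potential full-population risk per center.

    The fixed-effects outcome model is refit by stabilized
    inverse-propensity-weighted regression (Firth-corrected when ``firth``),
    then the plug-in standardization is evaluated on all n patients.  By the
    weighted score equations this plug-in coincides with the augmented
    (weighting + outcome-regression) form; the identity is asserted
    internally and a violation raises, as it signals broken score equations.
    Standard errors come from the sandwich over the stacked estimating
    equations (propensity score, weighted outcome score, standardization),
    with the stabilization factors n_c/n treated as known constants.
    """
    sw = stabilize_weights(psfit, registry)
    w = sw.weights
    if (w == 0).any():
        raise ValueError("zero stabilized weight encountered")
    wfit = fit_fe_logistic(registry, firth=firth, weights=w, interactions=interactions)
    F = _fe_risk_matrix(wfit, registry)
    est = F.mean(axis=0)

    # augmented form, Eq of the weighting+regression identity
    n, m = registry.n, registry.m
    codes = registry.center_codes
    g_own = psfit.prob_matrix[np.arange(n), codes]
    resid = registry.y - F[np.arange(n), codes]
    aug = est.copy()
    corr = np.bincount(codes, weights=resid / g_own, minlength=m) / n
    aug = est + corr
    if firth:
        # the Jeffreys penalty shifts the weighted score by a known amount
        shares = registry.center_sizes / n
        offset = _firth_score_offset(wfit, registry, w)
        aug_corrected = aug + offset / (n * shares)
        gap = np.max(np.abs(aug_corrected - est))
    else:
        gap = np.max(np.abs(aug - est))
    if gap > identity_tol:
        raise RuntimeError(
            f"augmented and plug-in standardized risks disagree by {gap:.2e} "
            f"(> {identity_tol:.0e}): weighted score equations not satisfied"
        )

    if compute_sd:
        sd = _dr_sandwich_sd(registry, psfit, wfit)
    else:
        sd = np.full(m, np.nan)
    diags = {"identity_gap": float(gap), "extreme_weights": len(sw.extreme)}
    return [
        StandardizedEstimate(c, float(est[i]), float(sd[i]), "dr_ps", dict(diags))
        for i, c in enumerate(wfit.centers)
    ]


def _dr_sandwich_sd(registry: Registry, psfit: PSFit, wfit: FEFit) -> np.ndarray:
    """Stacked M-estimation sandwich for the DR standardized risks.

    Parameter vector theta = (propensity coefficients, outcome coefficients,
    mu_1..mu_m); the bread is the numerical Jacobian of the averaged
    estimating function, the meat the empirical outer product of per-record
    contributions.
    """
    n, m = registry.n, registry.m
    codes = registry.center_codes
    y = registry.y
    Xps = (
        registry.data[psfit.covariate_cols].to_numpy(dtype=float)
        if psfit.covariate_cols
        else np.empty((n, 0))
    )
    X1 = np.hstack([np.ones((n, 1)), Xps])
    q = X1.shape[1]
    Xp, Xi = _split_design(registry, wfit.covariate_cols, wfit.interaction_cols)
    p0, p1 = Xp.shape[1], Xi.shape[1]
    d_out = p0 + p1 * m + m
    shares = registry.center_sizes / n
    onehot = np.zeros((n, m))
    onehot[np.arange(n), codes] = 1.0

    if psfit.form == "multinomial":
        ref = psfit.centers.index(psfit.reference_center)
        free = [c for c in range(m) if c != ref]
        theta_ps = np.concatenate([psfit.coefficients[c] for c in free])
        d_ps = len(free) * q
    else:
        free = list(range(m))
        theta_ps = psfit.coefficients.ravel()
        d_ps = m * q

    theta_out = wfit.params()
    mu_hat = _fe_risk_matrix(wfit, registry).mean(axis=0)
    theta = np.concatenate([theta_ps, theta_out, mu_hat])
    d_tot = d_ps + d_out + m

    # outcome design in (beta, gamma, psi) order for each record's own center
    Z_own = np.hstack(
        [Xp]
        + [Xi[:, [j]] * onehot for j in range(p1)]
        + [onehot]
    )

    def per_record_U(th: np.ndarray) -> np.ndarray:
        th_ps = th[:d_ps]
        th_out = th[d_ps : d_ps + d_out]
        mu = th[d_ps + d_out :]
        if psfit.form == "multinomial":
            coef = np.zeros((m, q))
            for b, c in enumerate(free):
                coef[c] = th_ps[b * q : (b + 1) * q]
            g = multinomial_prob_matrix(coef, X1)
            resid_ps = onehot - g
            U_ps = np.hstack([X1 * resid_ps[:, [c]] for c in free])
        else:
            coef = th_ps.reshape(m, q)
            raw = expit(X1 @ coef.T)
            U_ps = np.hstack([X1 * (onehot[:, [c]] - raw[:, [c]]) for c in range(m)])
            g = raw / raw.sum(axis=1, keepdims=True)
        g_own = g[np.arange(n), codes]
        wgt = shares[codes] / np.clip(g_own, 1e-300, None)
        beta = th_out[:p0]
        gamma = th_out[p0 : p0 + p1 * m].reshape(p1, m)
        psi = th_out[p0 + p1 * m :]
        eta0 = Xp @ beta if p0 else np.zeros(n)
        Fmat = np.empty((n, m))
        for c in range(m):
            eta = eta0 + psi[c]
            for j in range(p1):
                eta = eta + Xi[:, j] * gamma[j, c]
            Fmat[:, c] = expit(eta)
        f_own = Fmat[np.arange(n), codes]
        U_out = Z_own * (wgt * (y - f_own))[:, None]
        U_mu = Fmat - mu[None, :]
        return np.hstack([U_ps, U_out, U_mu])

    U0 = per_record_U(theta)
    B = U0.T @ U0 / n

    A = np.zeros((d_tot, d_tot))
    for j in range(d_tot):
        h = 1e-6 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        A[:, j] = (per_record_U(tp).mean(axis=0) - per_record_U(tm).mean(axis=0)) / (2 * h)

    Ainv = np.linalg.solve(A, np.eye(d_tot))
    V = Ainv @ B @ Ainv.T / n
    var_mu = np.diag(V)[d_ps + d_out :]
    return np.sqrt(np.clip(var_mu, 0, None))


# ---------------------------------------------------------------------------
# exact stratum-table oracle
# ---------------------------------------------------------------------------

def stratum_oracle(table: StratumTable) -> pd.DataFrame:
    """Closed-form standardization for a stratum table with known risks.

    Pure arithmetic, no model fitting: the direct risk weights each
    (pattern, center) risk by the pooled pattern frequency; the SMR and
    excess risk use each center's own pattern mix.  Requires a risk for
    every (pattern, center) pair.
    """
    df = table.data.copy()
    df["__center"] = df[table.center_col].astype(str)
    risks = df.pivot_table(
        index=table.pattern_cols, columns="__center", values=table.risk_col
    )
    counts = df.pivot_table(
        index=table.pattern_cols,
        columns="__center",
        values=table.count_col,
        fill_value=0,
    )
    centers = table.centers
    risks = risks[centers]
    counts = counts[centers].astype(float)
    if risks.isna().any().any():
        pat, cen = np.argwhere(risks.isna().to_numpy())[0]
        raise ValueError(
            f"missing risk for pattern {risks.index[pat]!r}, center {centers[cen]!r}"
        )
    R = risks.to_numpy()                       # patterns x centers
    Nmat = counts.to_numpy()
    pooled = Nmat.sum(axis=1)                  # pooled pattern counts
    N = pooled.sum()
    direct = (pooled[:, None] * R).sum(axis=0) / N
    n_c = Nmat.sum(axis=0)
    mix = Nmat / n_c[None, :]                  # own pattern mix per center
    expected = mix.T @ R                       # (c, c*): center c's mix under c*
    observed = np.diag(expected)
    denom = expected.mean(axis=1)
    if (denom == 0).any():
        raise ZeroDivisionError("zero expected risk in SMR denominator")
    out = pd.DataFrame(
        {
            "center": centers,
            "n_c": n_c.astype(int),
            "observed_risk": observed,
            "direct_risk": direct,
            "smr": observed / denom,
            "excess_risk": observed - denom,
        }
    ).set_index("center")
    return out
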