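"""Propensity of treatment at each center and stabilized inverse weights.

The propensity score here is the vector of probabilities that a patient with
baseline covariates L is treated at each of the m centers.  Two estimators
are provided: a multinomial logistic model with one reference center, and
the one-vs-rest approximation (a separate logistic model per center with the
fitted probabilities renormalized to sum to one across centers) that remains
usable when the multinomial fit fails to converge for large m.  Weights are
stabilized by each center's patient share n_c / n; extreme weights are
reported, never trimmed by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .registry_io import Registry

__all__ = [
    "PSFit",
    "StabilizedWeights",
    "fit_ps_multinomial",
    "fit_ps_per_center",
    "stabilize_weights",
    "ps_overlap_report",
    "PSConvergenceError",
]


class PSConvergenceError(RuntimeError):
    pass


@dataclass
class PSFit:
    """Fitted center-membership probability model.

    ``coefficients`` is an m x (1+p) array of (intercept, slopes) per center;
    for the multinomial form the reference center's row is fixed at zero.
    ``prob_matrix`` holds fitted probabilities g(L_i, c), each row summing
    to one (for the one-vs-rest form, after renormalization).
    """

    form: str                        # "multinomial" | "per_center_logistic"
    coefficients: np.ndarray         # (m, 1+p)
    prob_matrix: np.ndarray          # (n, m)
    centers: list[str]
    covariate_cols: list[str]
    reference_center: str | None = None
    stabilization_factors: np.ndarray | None = None  # n_c / n
    stabilized: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.centers)

    def prob_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.prob_matrix, columns=self.centers)


@dataclass
class StabilizedWeights:
    """Per-record stabilized inverse-propensity weights with diagnostics."""

    weights: np.ndarray
    extreme: pd.DataFrame            # rows flagged above the cap percentile
    cap_percentile: float
    stabilized: bool = True

    def __len__(self) -> int:
        return len(self.weights)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.weights, dtype=dtype)


def _ps_design(registry: Registry) -> np.ndarray:
    return np.hstack([np.ones((registry.n, 1)), registry.X])


def multinomial_prob_matrix(
    coefficients: np.ndarray, X1: np.ndarray
) -> np.ndarray:
    """Softmax probabilities from (m, 1+p) coefficients and (n, 1+p) design."""
    eta = X1 @ coefficients.T
    eta -= eta.max(axis=1, keepdims=True)
    g = np.exp(eta)
    g /= g.sum(axis=1, keepdims=True)
    return g


def multinomial_score(
    coefficients: np.ndarray, X1: np.ndarray, codes: np.ndarray, ref: int
) -> np.ndarray:
    """Mean score of the multinomial likelihood for the non-reference centers.

    Stacked per center c != ref:  (1/n) sum_i (1, L_i) {I(C_i=c) - g_ic}.
    """
    n, m = len(X1), len(coefficients)
    g = multinomial_prob_matrix(coefficients, X1)
    onehot = np.zeros((n, m))
    onehot[np.arange(n), codes] = 1.0
    resid = onehot - g
    blocks = [X1.T @ resid[:, c] / n for c in range(m) if c != ref]
    return np.concatenate(blocks)


def fit_ps_multinomial(
    registry: Registry,
    reference_center: str | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> PSFit:
    """Maximum-likelihood multinomial logistic propensity model.

    The reference center's coefficients are fixed at zero; the score
    equations are satisfied to better than 1e-6 in max norm at return, else
    a convergence error recommends the one-vs-rest form.
    """
    if (registry.center_sizes == 0).any():
        raise ValueError("every center needs at least one record")
    X1 = _ps_design(registry)
    codes = registry.center_codes
    n, q = X1.shape
    m = registry.m
    ref = 0 if reference_center is None else registry.centers.index(reference_center)
    free = [c for c in range(m) if c != ref]
    d = len(free) * q

    onehot = np.zeros((n, m))
    onehot[np.arange(n), codes] = 1.0

    theta = np.zeros(d)
    shares = registry.center_sizes / n
    for b, c in enumerate(free):
        theta[b * q] = np.log(shares[c] / shares[ref])

    def unpack(th):
        coef = np.zeros((m, q))
        for b, c in enumerate(free):
            coef[c] = th[b * q : (b + 1) * q]
        return coef

    def loglik(th):
        g = multinomial_prob_matrix(unpack(th), X1)
        return float(np.sum(np.log(np.clip(g[np.arange(n), codes], 1e-300, None))))

    ll_cur = loglik(theta)
    converged = False
    for _ in range(max_iter):
        g = multinomial_prob_matrix(unpack(theta), X1)
        resid = onehot - g
        U = np.concatenate([X1.T @ resid[:, c] for c in free])
        if np.max(np.abs(U)) < max(tol * n, 1e-9):
            converged = True
            break
        # observed information blocks: H[cd] = X' diag(g_c (delta_cd - g_d)) X
        H = np.zeros((d, d))
        for a, c in enumerate(free):
            for b_, c2 in enumerate(free):
                wcc = g[:, c] * ((c == c2) - g[:, c2])
                H[a * q : (a + 1) * q, b_ * q : (b_ + 1) * q] = X1.T @ (X1 * wcc[:, None])
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(d), U)
        except np.linalg.LinAlgError as exc:
            raise PSConvergenceError(
                "multinomial information singular; consider fit_ps_per_center"
            ) from exc
        alpha = 1.0
        for _ in range(30):
            ll_new = loglik(theta + alpha * step)
            if ll_new >= ll_cur - 1e-10:
                break
            alpha *= 0.5
        theta = theta + alpha * step
        ll_cur = ll_new
        if np.max(np.abs(theta)) > 40:
            break
    if not converged:
        raise PSConvergenceError(
            "multinomial propensity model did not converge (common for large m); "
            "use fit_ps_per_center instead"
        )
    coef = unpack(theta)
    g = multinomial_prob_matrix(coef, X1)
    return PSFit(
        form="multinomial",
        coefficients=coef,
        prob_matrix=g,
        centers=list(registry.centers),
        covariate_cols=list(registry.covariate_cols),
        reference_center=registry.centers[ref],
        stabilization_factors=registry.center_sizes / n,
    )


def _logistic_newton(
    X1: np.ndarray, y: np.ndarray, firth: bool, tol: float = 1e-10, max_iter: int = 100
) -> tuple[np.ndarray, bool]:
    q = X1.shape[1]
    beta = np.zeros(q)
    beta[0] = np.log((y.sum() + 0.5) / (len(y) - y.sum() + 0.5))
    for _ in range(max_iter):
        p = expit(X1 @ beta)
        W = p * (1 - p)
        I = X1.T @ (X1 * W[:, None])
        resid = y - p
        if firth:
            ZI = np.linalg.solve(I, X1.T)
            h = W * np.einsum("ij,ji->i", X1, ZI)
            resid = resid + h * (0.5 - p)
        U = X1.T @ resid
        if np.max(np.abs(U)) < max(tol * len(y), 1e-10):
            return beta, True
        try:
            beta = beta + np.linalg.solve(I + 1e-12 * np.eye(q), U)
        except np.linalg.LinAlgError:
            return beta, False
        if not firth and np.max(np.abs(beta)) > 30:
            return beta, False
    return beta, False


def per_center_prob_matrix(coefficients: np.ndarray, X1: np.ndarray) -> np.ndarray:
    """One-vs-rest probabilities renormalized so each row sums to one."""
    raw = expit(X1 @ coefficients.T)
    return raw / raw.sum(axis=1, keepdims=True)


def fit_ps_per_center(registry: Registry) -> PSFit:
    """One-vs-rest logistic propensity fit, one model per center.

    Each center's membership indicator is regressed on the same covariates
    as the multinomial form; fitted probabilities are divided by the row sum
    over all m centers.  A center whose one-vs-rest fit separates is refit
    with Firth correction, with a note recorded on the returned fit.
    """
    sizes = registry.center_sizes
    if (sizes == 0).any() or (sizes == registry.n).any():
        raise ValueError("each center needs >= 1 member and >= 1 non-member")
    X1 = _ps_design(registry)
    m = registry.m
    coef = np.zeros((m, X1.shape[1]))
    notes: list[str] = []
    for c in range(m):
        yc = (registry.center_codes == c).astype(float)
        beta, ok = _logistic_newton(X1, yc, firth=False)
        if not ok:
            beta, ok = _logistic_newton(X1, yc, firth=True)
            notes.append(
                f"center {registry.centers[c]!r}: separation in one-vs-rest fit; "
                f"Firth-corrected refit used"
            )
        coef[c] = beta
    prob = per_center_prob_matrix(coef, X1)
    return PSFit(
        form="per_center_logistic",
        coefficients=coef,
        prob_matrix=prob,
        centers=list(registry.centers),
        covariate_cols=list(registry.covariate_cols),
        stabilization_factors=sizes / registry.n,
        notes=notes,
    )


def stabilize_weights(
    psfit: PSFit, registry: Registry, cap_percentile: float = 99.0
) -> StabilizedWeights:
    """Stabilized weight (n_c / n) / g(L_i, C_i) for every record.

    Stabilization divides the raw inverse-propensity weight by the inverse
    patient share of the record's own center, so weights average near one.
    Weights above the ``cap_percentile`` quantile are reported in the
    ``extreme`` table but not truncated.
    """
    if psfit.prob_matrix.shape[0] != registry.n:
        raise ValueError("psfit was not computed on this registry")
    g_own = psfit.prob_matrix[np.arange(registry.n), registry.center_codes]
    if (g_own <= 0).any():
        i = int(np.argmin(g_own))
        raise ZeroDivisionError(
            f"fitted propensity is numerically zero for record {i} "
            f"(center {registry.centers[registry.center_codes[i]]!r})"
        )
    shares = registry.center_sizes / registry.n
    w = shares[registry.center_codes] / g_own
    cut = np.percentile(w, cap_percentile)
    flagged = np.flatnonzero(w > max(cut, 10.0))
    extreme = pd.DataFrame(
        {
            "record": flagged,
            "center": [registry.centers[c] for c in registry.center_codes[flagged]],
            "weight": w[flagged],
            "propensity": g_own[flagged],
        }
    )
    psfit.stabilized = True
    return StabilizedWeights(weights=w, extreme=extreme, cap_percentile=cap_percentile)


def ps_overlap_report(
    psfit: PSFit,
    registry: Registry,
    low_ps_threshold: float = 0.01,
    percentile: float = 5.0,
) -> pd.DataFrame:
    """Per-center overlap diagnostics on each center's own patients.

    Small centers with case-mix far from the rest can have problematically
    small own-center propensities; the ``flagged`` column marks centers whose
    minimum own-patient propensity falls below ``low_ps_threshold``.
    """
    rows = []
    shares = registry.center_sizes / registry.n
    for c, name in enumerate(registry.centers):
        own = psfit.prob_matrix[registry.center_codes == c, c]
        w = shares[c] / own
        rows.append(
            {
                "center": name,
                "n_c": int(registry.center_sizes[c]),
                "min_ps": float(own.min()),
                f"p{percentile:g}_ps": float(np.percentile(own, percentile)),
                "n_below_threshold": int((own < low_ps_threshold).sum()),
                "weight_mean": float(w.mean()),
                "weight_max": float(w.max()),
                "flagged": bool(own.min() < low_ps_threshold),
            }
        )
    return pd.DataFrame(rows)
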