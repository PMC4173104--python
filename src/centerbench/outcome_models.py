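"""Outcome regression E(Y | L, C) with fixed or random center effects.

Three formulations of the logistic outcome model

    E(Y | L, C=c) = expit(L' beta + psi_c)

are supported:

* fixed center effects, fit by (optionally weighted) maximum likelihood or
  by Firth's penalized likelihood  l(beta, psi) + 1/2 log |I(beta, psi)|,
  which keeps estimates finite under separation and reduces the O(1/n)
  small-sample bias;
* a Bayesian normal mixed-effects model, psi_c ~ N(mu_psi, sigma_psi^2);
* a clustered mixed-effects model where the psi_c follow a K-component
  normal mixture with unknown weights (centers have equal prior probability
  of belonging to each cluster).

The design uses m center indicator columns and no global intercept, so each
psi_c absorbs the intercept for its center.  Covariates listed in
``interactions`` receive a separate coefficient per center (the hook that
yields a fully saturated model on stratum-expanded data).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr
from scipy.special import expit

from .registry_io import Registry

__all__ = [
    "FEFit",
    "MEDraws",
    "fit_fe_logistic",
    "fit_me_normal",
    "fit_me_clustered",
    "predict_risk",
    "ConvergenceError",
    "RankDeficiencyError",
]


class ConvergenceError(RuntimeError):
    pass


class RankDeficiencyError(ValueError):
    pass


def _log1pexp(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


# ---------------------------------------------------------------------------
# fixed effects
# ---------------------------------------------------------------------------

@dataclass
class FEFit:
    """Fitted fixed-center-effects logistic regression.

    Parameter order in ``information`` is (beta, gamma row-major, psi):
    plain covariate coefficients, then per-center coefficients for each
    interaction covariate, then the m center effects.
    """

    beta: np.ndarray                 # (p0,) plain covariate coefficients
    gamma: np.ndarray                # (p1, m) per-center interaction coefficients
    psi: np.ndarray                  # (m,) center effects
    information: np.ndarray          # observed Fisher information at optimum
    centers: list[str]
    covariate_cols: list[str]
    interaction_cols: list[str]
    firth: bool
    converged: bool
    n_iter: int
    grad_norm: float
    weights_used: np.ndarray | None = None
    diverging: list[str] = field(default_factory=list)
    loglik: float = np.nan

    @property
    def m(self) -> int:
        return len(self.centers)

    @property
    def n_params(self) -> int:
        return len(self.beta) + self.gamma.size + self.m

    def params(self) -> np.ndarray:
        return np.concatenate([self.beta, self.gamma.ravel(), self.psi])

    def linear_predictor(
        self, X_plain: np.ndarray, X_int: np.ndarray, center_code: np.ndarray | int
    ) -> np.ndarray:
        """eta_i under center assignment ``center_code`` (scalar or per-record)."""
        eta = X_plain @ self.beta if self.beta.size else np.zeros(len(X_plain))
        if np.isscalar(center_code):
            eta = eta + self.psi[center_code]
            for j in range(len(self.interaction_cols)):
                eta = eta + X_int[:, j] * self.gamma[j, center_code]
        else:
            eta = eta + self.psi[center_code]
            for j in range(len(self.interaction_cols)):
                eta = eta + X_int[:, j] * self.gamma[j, center_code]
        return eta

    def predicted_risk(self, registry: Registry, center: int | None = None) -> np.ndarray:
        """Fitted risks; ``center=None`` uses each record's own center."""
        Xp, Xi = _split_design(registry, self.covariate_cols, self.interaction_cols)
        code = registry.center_codes if center is None else center
        return expit(self.linear_predictor(Xp, Xi, code))

    def to_json(self, path) -> None:
        payload = {
            "centers": self.centers,
            "covariate_cols": self.covariate_cols,
            "interaction_cols": self.interaction_cols,
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
            "psi": self.psi.tolist(),
            "information": self.information.tolist(),
            "firth": self.firth,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "loglik": self.loglik,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _split_design(
    registry: Registry, covariate_cols: list[str], interaction_cols: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    df = registry.data
    Xp = (
        df[covariate_cols].to_numpy(dtype=float)
        if covariate_cols
        else np.empty((registry.n, 0))
    )
    Xi = (
        df[interaction_cols].to_numpy(dtype=float)
        if interaction_cols
        else np.empty((registry.n, 0))
    )
    return Xp, Xi


def build_design(
    registry: Registry, interactions: list[str] | None = None
) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Full design: plain covariates | per-center interaction dummies | center indicators."""
    interactions = list(interactions or [])
    plain = [c for c in registry.covariate_cols if c not in interactions]
    Xp, Xi = _split_design(registry, plain, interactions)
    n, m = registry.n, registry.m
    centers_onehot = np.zeros((n, m))
    centers_onehot[np.arange(n), registry.center_codes] = 1.0
    blocks = [Xp]
    names = list(plain)
    for j, col in enumerate(interactions):
        blocks.append(Xi[:, [j]] * centers_onehot)
        names += [f"{col}:{c}" for c in registry.centers]
    blocks.append(centers_onehot)
    names += [f"center[{c}]" for c in registry.centers]
    return np.hstack(blocks), names, plain, interactions


def _check_rank(Z: np.ndarray, names: list[str]) -> None:
    if Z.shape[1] == 0:
        return
    _, R, piv = qr(Z, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(Z.shape) * np.finfo(float).eps if d.size else 0.0
    bad = piv[np.flatnonzero(d < tol)] if d.size else []
    rank = int((d >= tol).sum())
    if rank < Z.shape[1]:
        aliased = [names[i] for i in piv[rank:]] + [names[i] for i in bad]
        raise RankDeficiencyError(
            f"design matrix rank-deficient; aliased columns: {sorted(set(aliased))}"
        )


def fit_fe_logistic(
    registry: Registry,
    firth: bool = False,
    weights: np.ndarray | None = None,
    interactions: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FEFit:
    """Fit the fixed-effects logistic outcome model by (penalized) ML.

    Newton iteration on the score; with ``firth=True`` the score is modified
    by the hat-diagonal term  h_i (1/2 - p_i)  so the optimum maximizes the
    Jeffreys-penalized likelihood.  Weights (e.g. stabilized inverse
    propensity weights) enter both the likelihood and the information.
    Non-convergence is reported on the returned fit, never silently
    truncated; with ``firth=False`` complete or quasi-complete separation
    surfaces as ``converged=False`` with the diverging parameters named.
    """
    Z, names, plain, inter = build_design(registry, interactions)
    _check_rank(Z, names)
    y = registry.y
    n, d = Z.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")

    theta = np.zeros(d)
    # start center effects at empirical logits for speed and robustness
    sizes = registry.center_sizes.astype(float)
    events = np.bincount(registry.center_codes, weights=y, minlength=registry.m)
    theta[-registry.m:] = np.log(
        (events + 0.5) / (sizes - events + 0.5)
    )

    def penalized_loglik(th):
        eta = Z @ th
        ll = float(np.sum(w * (y * eta - _log1pexp(eta))))
        if not firth:
            return ll, None
        p = expit(eta)
        W = w * p * (1 - p)
        I = Z.T @ (Z * W[:, None])
        sign, logdet = np.linalg.slogdet(I)
        if sign <= 0:
            return -np.inf, None
        return ll + 0.5 * logdet, I

    ll_cur, _ = penalized_loglik(theta)
    grad_norm = np.inf
    best_grad = np.inf
    stalled = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Z @ theta
        p = expit(eta)
        W = w * p * (1 - p)
        I = Z.T @ (Z * W[:, None])
        resid = w * (y - p)
        if firth:
            # h_i = W_i z_i' I^{-1} z_i  (hat diagonal of the weighted design)
            try:
                ZI = np.linalg.solve(I, Z.T)
            except np.linalg.LinAlgError:
                ZI = np.linalg.lstsq(I, Z.T, rcond=None)[0]
            h = W * np.einsum("ij,ji->i", Z, ZI)
            resid = resid + h * (0.5 - p)
        U = Z.T @ resid
        grad_norm = float(np.max(np.abs(U))) if d else 0.0
        if grad_norm < tol:
            converged = True
            break
        if grad_norm < 1e-6:
            stalled += 1
            if stalled >= 15:
                converged = True   # gradient oscillates within precision
                break
        best_grad = min(best_grad, grad_norm)
        try:
            step = np.linalg.solve(I + 1e-12 * np.eye(d), U)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(I, U, rcond=None)[0]
        # step-halving line search on the (penalized) log-likelihood
        alpha = 1.0
        for _ in range(30):
            cand = theta + alpha * step
            ll_new, _ = penalized_loglik(cand)
            if ll_new >= ll_cur - 1e-12:
                break
            alpha *= 0.5
        theta = theta + alpha * step
        if np.max(np.abs(alpha * step)) < 1e-10 and grad_norm < 1e-6:
            converged = True   # stalled within numerical precision
            break
        ll_cur = ll_new
        if not firth and np.max(np.abs(theta)) > 30:
            break  # diverging: (quasi-)separation

    if converged and not firth and np.max(np.abs(theta)) > 15:
        # gradient vanished in the tail of the likelihood: the MLE is at
        # infinity (complete or quasi-complete separation / empty cells)
        converged = False
    eta = Z @ theta
    p = expit(eta)
    W = w * p * (1 - p)
    I = Z.T @ (Z * W[:, None])
    diverging = []
    if not converged:
        diverging = [names[j] for j in np.flatnonzero(np.abs(theta) > 10)]
        warnings.warn(
            f"fixed-effects logistic fit did not converge "
            f"(grad max-norm {grad_norm:.3g}); diverging: {diverging or 'none'}"
        )
    p0, p1, m = len(plain), len(inter), registry.m
    beta = theta[:p0]
    gamma = theta[p0 : p0 + p1 * m].reshape(p1, m)
    psi = theta[p0 + p1 * m :]
    return FEFit(
        beta=beta,
        gamma=gamma,
        psi=psi,
        information=I,
        centers=list(registry.centers),
        covariate_cols=plain,
        interaction_cols=inter,
        firth=firth,
        converged=converged,
        n_iter=it,
        grad_norm=grad_norm,
        weights_used=None if weights is None else w,
        diverging=diverging,
        loglik=float(np.sum(w * (y * eta - _log1pexp(eta)))),
    )


def predict_risk(fit, covariates, center) -> float:
    """Risk expit(L' beta + psi_c) for one covariate vector at one center.

    ``fit`` may be an :class:`FEFit` or a single posterior draw represented
    as a mapping with ``beta`` and ``psi`` arrays (and ``centers`` labels).
    """
    x = np.atleast_1d(np.asarray(covariates, dtype=float))
    if isinstance(fit, FEFit):
        centers = fit.centers
        if center not in centers:
            raise KeyError(f"unknown center {center!r}")
        c = centers.index(center)
        ncov = len(fit.covariate_cols) + len(fit.interaction_cols)
        if x.size != ncov:
            raise ValueError(f"expected {ncov} covariates, got {x.size}")
        xp = x[: len(fit.covariate_cols)]
        xi = x[len(fit.covariate_cols):]
        eta = float(xp @ fit.beta) + fit.psi[c]
        for j in range(len(fit.interaction_cols)):
            eta += xi[j] * fit.gamma[j, c]
        return float(expit(eta))
    centers = list(fit["centers"])
    if center not in centers:
        raise KeyError(f"unknown center {center!r}")
    c = centers.index(center)
    beta = np.asarray(fit["beta"], dtype=float)
    eta = float(x @ beta) + float(np.asarray(fit["psi"])[c])
    return float(expit(eta))


# ---------------------------------------------------------------------------
# Bayesian mixed effects (adaptive Metropolis-within-Gibbs)
# ---------------------------------------------------------------------------

DEFAULT_PRIORS = {
    "beta_sd": 10.0,       # beta_j ~ N(0, beta_sd^2)
    "mu_sd": 10.0,         # mu_psi (and cluster means) ~ N(0, mu_sd^2)
    "sigma_scale": 1.0,    # sigma_psi (and cluster sds) ~ half-normal(sigma_scale)
    "dirichlet": 1.0,      # mixture weights ~ symmetric Dirichlet
}

DEFAULT_MCMC = {"chains": 4, "warmup": 1000, "draws": 1000, "thin": 1, "seed": 0,
                "rhat_threshold": 1.01}


@dataclass
class MEDraws:
    """Posterior draws from a mixed-effects outcome model.

    Arrays are shaped (chains, draws, ...).  For the clustered variant the
    mixture blocks are present and clusters are relabeled by ascending
    cluster mean in every draw, which resolves label switching.
    """

    beta: np.ndarray          # (C, S, p)
    psi: np.ndarray           # (C, S, m)
    mu_psi: np.ndarray        # (C, S) -- population mean (weighted mixture mean if K>1)
    sigma_psi: np.ndarray     # (C, S) -- population sd (mixture sd if K>1)
    centers: list[str]
    covariate_cols: list[str]
    diagnostics: dict
    K: int = 1
    mu_k: np.ndarray | None = None      # (C, S, K)
    sigma_k: np.ndarray | None = None   # (C, S, K)
    p_k: np.ndarray | None = None       # (C, S, K)
    z: np.ndarray | None = None         # (C, S, m) cluster assignment

    @property
    def m(self) -> int:
        return len(self.centers)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def posterior_mean_psi(self) -> np.ndarray:
        return self.stacked("psi").mean(axis=0)

    def to_frame(self):
        """Columnar draws (one row per kept draw across chains)."""
        import pandas as pd

        cols = {}
        b = self.stacked("beta")
        for j, name in enumerate(self.covariate_cols):
            cols[f"beta[{name}]"] = b[:, j]
        ps = self.stacked("psi")
        for c, name in enumerate(self.centers):
            cols[f"psi[{name}]"] = ps[:, c]
        cols["mu_psi"] = self.stacked("mu_psi")
        cols["sigma_psi"] = self.stacked("sigma_psi")
        if self.K > 1:
            for k in range(self.K):
                cols[f"mu_k[{k}]"] = self.stacked("mu_k")[:, k]
                cols[f"sigma_k[{k}]"] = self.stacked("sigma_k")[:, k]
                cols[f"p_k[{k}]"] = self.stacked("p_k")[:, k]
        return pd.DataFrame(cols)


def _me_diagnostics(store: dict, threshold: float) -> dict:
    """Split-chain R-hat and bulk ESS via arviz."""
    import arviz as az

    posterior = {k: v for k, v in store.items() if v is not None}
    idata = az.from_dict(posterior=posterior)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    max_rhat = float(
        max(np.nanmax(np.atleast_1d(rhat[v].values)) for v in rhat.data_vars)
    )
    min_ess = float(
        min(np.nanmin(np.atleast_1d(ess[v].values)) for v in ess.data_vars)
    )
    diag = {"max_rhat": max_rhat, "min_ess_bulk": min_ess}
    if max_rhat > threshold:
        warnings.warn(
            f"MCMC convergence statistic {max_rhat:.3f} exceeds "
            f"threshold {threshold}; draws returned with diagnostics"
        )
    return diag


def _run_me_sampler(
    registry: Registry,
    K: int,
    priors: dict,
    mcmc: dict,
) -> MEDraws:
    pri = {**DEFAULT_PRIORS, **(priors or {})}
    cfg = {**DEFAULT_MCMC, **(mcmc or {})}
    chains, warmup, draws, thin = (
        int(cfg["chains"]), int(cfg["warmup"]), int(cfg["draws"]), int(cfg["thin"])
    )
    X = registry.X
    y = registry.y
    codes = registry.center_codes
    n, p = X.shape
    m = registry.m
    sizes = registry.center_sizes.astype(float)
    events = np.bincount(codes, weights=y, minlength=m)
    psi_init = np.log((events + 0.5) / (sizes - events + 0.5))

    beta_var = pri["beta_sd"] ** 2
    mu_var = pri["mu_sd"] ** 2
    sig_scale = pri["sigma_scale"]
    alpha0 = pri["dirichlet"]

    n_kept = draws // thin
    S_beta = np.empty((chains, n_kept, p))
    S_psi = np.empty((chains, n_kept, m))
    S_mu = np.empty((chains, n_kept))
    S_sig = np.empty((chains, n_kept))
    S_muk = np.empty((chains, n_kept, K)) if K > 1 else None
    S_sigk = np.empty((chains, n_kept, K)) if K > 1 else None
    S_pk = np.empty((chains, n_kept, K)) if K > 1 else None
    S_z = np.empty((chains, n_kept, m), dtype=np.int8) if K > 1 else None
    acc_stats = []

    ss = np.random.SeedSequence(int(cfg["seed"]))
    for chain, child in enumerate(ss.spawn(chains)):
        rng = np.random.default_rng(child)
        beta = rng.normal(0, 0.1, p)
        psi = psi_init + rng.normal(0, 0.1, m)
        mu_k = np.sort(rng.normal(psi.mean(), 0.5, K))
        sigma_k = np.full(K, max(psi.std(), 0.3))
        p_k = np.full(K, 1.0 / K)
        z = rng.integers(0, K, m)

        eta0 = X @ beta if p else np.zeros(n)
        eta = eta0 + psi[codes]
        lp_i = y * eta - _log1pexp(eta)     # per-record log-likelihood, cached

        ls_psi = np.full(m, np.log(2.4 / np.sqrt(sizes + 1)))
        ls_beta = np.full(p, np.log(0.1))
        ls_sig = np.full(K, np.log(0.3))
        acc_psi = np.zeros(m)
        acc_beta = np.zeros(p)
        n_acc_steps = 0

        total = warmup + draws
        kept = 0
        for t in range(total):
            adapt = t < warmup
            gam = (t + 1) ** -0.6

            # --- psi: independent per-center random-walk MH, vectorized
            prop = psi + np.exp(ls_psi) * rng.standard_normal(m)
            eta_new = eta0 + prop[codes]
            lp_new = y * eta_new - _log1pexp(eta_new)
            dll = np.bincount(codes, weights=lp_new - lp_i, minlength=m)
            pm, psd = mu_k[z], sigma_k[z]
            dprior = -0.5 * ((prop - pm) ** 2 - (psi - pm) ** 2) / psd**2
            acc = np.log(rng.random(m)) < dll + dprior
            psi = np.where(acc, prop, psi)
            if acc.any():
                mask = acc[codes]
                eta[mask] = eta_new[mask]
                lp_i[mask] = lp_new[mask]
            if adapt:
                ls_psi += gam * (acc.astype(float) - 0.44)
            else:
                acc_psi += acc
                n_acc_steps += 1

            # --- beta: per-coordinate random-walk MH
            for j in range(p):
                bj = beta[j] + np.exp(ls_beta[j]) * rng.standard_normal()
                eta_new = eta + (bj - beta[j]) * X[:, j]
                lp_new = y * eta_new - _log1pexp(eta_new)
                dll = float(np.sum(lp_new - lp_i))
                dpr = -0.5 * (bj**2 - beta[j] ** 2) / beta_var
                ok = np.log(rng.random()) < dll + dpr
                if ok:
                    eta0 = eta0 + (bj - beta[j]) * X[:, j]
                    eta, lp_i, beta[j] = eta_new, lp_new, bj
                if adapt:
                    ls_beta[j] += gam * (float(ok) - 0.44)
                else:
                    acc_beta[j] += float(ok)

            if K > 1:
                # --- z: Gibbs over cluster assignments
                logw = (
                    np.log(p_k)[None, :]
                    - np.log(sigma_k)[None, :]
                    - 0.5 * (psi[:, None] - mu_k[None, :]) ** 2 / sigma_k[None, :] ** 2
                )
                logw -= logw.max(axis=1, keepdims=True)
                wgt = np.exp(logw)
                wgt /= wgt.sum(axis=1, keepdims=True)
                u = rng.random(m)[:, None]
                z = (u > np.cumsum(wgt, axis=1)).sum(axis=1)
                counts = np.bincount(z, minlength=K).astype(float)
                # --- p: Dirichlet Gibbs
                p_k = rng.dirichlet(alpha0 + counts)
                # --- mu_k: conjugate normal given assignments
                ssum = np.bincount(z, weights=psi, minlength=K)
                prec = counts / sigma_k**2 + 1.0 / mu_var
                mu_k = ssum / sigma_k**2 / prec + rng.standard_normal(K) / np.sqrt(prec)
                # --- sigma_k: MH on log scale, half-normal prior
                for k in range(K):
                    lsk = np.log(sigma_k[k]) + np.exp(ls_sig[k]) * rng.standard_normal()
                    sk = np.exp(lsk)
                    idx = z == k
                    r2 = float(np.sum((psi[idx] - mu_k[k]) ** 2))
                    cur = sigma_k[k]
                    logr = (
                        -counts[k] * (lsk - np.log(cur))
                        - 0.5 * r2 * (1 / sk**2 - 1 / cur**2)
                        - 0.5 * (sk**2 - cur**2) / sig_scale**2
                        + (lsk - np.log(cur))  # Jacobian of log transform
                    )
                    ok = np.log(rng.random()) < logr
                    if ok:
                        sigma_k[k] = sk
                    if adapt:
                        ls_sig[k] += gam * (float(ok) - 0.44)
            else:
                # --- mu_psi: conjugate normal
                prec = m / sigma_k[0] ** 2 + 1.0 / mu_var
                mean = psi.sum() / sigma_k[0] ** 2 / prec
                mu_k[0] = mean + rng.standard_normal() / np.sqrt(prec)
                # --- sigma_psi: MH on log scale with half-normal prior
                lsk = np.log(sigma_k[0]) + np.exp(ls_sig[0]) * rng.standard_normal()
                sk = np.exp(lsk)
                r2 = float(np.sum((psi - mu_k[0]) ** 2))
                cur = sigma_k[0]
                logr = (
                    -m * (lsk - np.log(cur))
                    - 0.5 * r2 * (1 / sk**2 - 1 / cur**2)
                    - 0.5 * (sk**2 - cur**2) / sig_scale**2
                    + (lsk - np.log(cur))
                )
                ok = np.log(rng.random()) < logr
                if ok:
                    sigma_k[0] = sk
                if adapt:
                    ls_sig[0] += gam * (float(ok) - 0.44)

            if not adapt and (t - warmup) % thin == 0 and kept < n_kept:
                if K > 1:
                    order = np.argsort(mu_k)
                    inv = np.empty(K, dtype=int)
                    inv[order] = np.arange(K)
                    S_muk[chain, kept] = mu_k[order]
                    S_sigk[chain, kept] = sigma_k[order]
                    S_pk[chain, kept] = p_k[order]
                    S_z[chain, kept] = inv[z]
                    pk_o, mk_o, sk_o = p_k[order], mu_k[order], sigma_k[order]
                    mbar = float(pk_o @ mk_o)
                    S_mu[chain, kept] = mbar
                    S_sig[chain, kept] = float(
                        np.sqrt(pk_o @ (sk_o**2 + (mk_o - mbar) ** 2))
                    )
                else:
                    S_mu[chain, kept] = mu_k[0]
                    S_sig[chain, kept] = sigma_k[0]
                S_beta[chain, kept] = beta
                S_psi[chain, kept] = psi
                kept += 1
        acc_stats.append(
            {
                "psi_accept_mean": float(np.mean(acc_psi / max(n_acc_steps, 1))),
                "beta_accept_mean": float(np.mean(acc_beta / max(draws, 1))) if p else None,
            }
        )

    store = {"mu_psi": S_mu, "sigma_psi": S_sig, "psi": S_psi}
    if p:
        store["beta"] = S_beta
    diag = _me_diagnostics(store, float(cfg["rhat_threshold"]))
    diag["acceptance"] = acc_stats
    if K > 1:
        occupied = np.array(
            [np.any(S_z.reshape(-1, m) == k) for k in range(K)]
        )
        if not occupied.all():
            empty = list(np.flatnonzero(~occupied))
            diag["empty_clusters"] = empty
    return MEDraws(
        beta=S_beta,
        psi=S_psi,
        mu_psi=S_mu,
        sigma_psi=S_sig,
        centers=list(registry.centers),
        covariate_cols=list(registry.covariate_cols),
        diagnostics=diag,
        K=K,
        mu_k=S_muk,
        sigma_k=S_sigk,
        p_k=S_pk,
        z=S_z,
    )


def fit_me_normal(
    registry: Registry, priors: dict | None = None, mcmc: dict | None = None
) -> MEDraws:
    """Bayesian normal mixed-effects fit: psi_c ~ N(mu_psi, sigma_psi^2).

    Posterior sampled by an adaptive Metropolis-within-Gibbs scheme:
    vectorized per-center random-walk updates for psi, per-coordinate updates
    for beta, a conjugate Gibbs step for mu_psi and a log-scale MH step for
    sigma_psi (half-normal prior).  Seed-reproducible; split-chain R-hat and
    bulk ESS are reported in ``diagnostics``.
    """
    if registry.m < 3:
        raise ValueError("mixed-effects fit needs m >= 3 centers "
                         "(sigma_psi weakly identified below)")
    return _run_me_sampler(registry, K=1, priors=priors or {}, mcmc=mcmc or {})


def fit_me_clustered(
    registry: Registry, K: int, priors: dict | None = None, mcmc: dict | None = None
) -> MEDraws:
    """Clustered mixed-effects fit: psi_c from a K-component normal mixture.

    Each center has equal prior probability of belonging to each cluster;
    mixture weights get a symmetric Dirichlet prior.  Label switching is
    resolved by reordering clusters by ascending cluster mean in every kept
    draw.  ``K=1`` reduces to the plain normal mixed-effects model.
    """
    if not 1 <= K < registry.m:
        raise ValueError(f"need 1 <= K < m, got K={K}, m={registry.m}")
    return _run_me_sampler(registry, K=K, priors=priors or {}, mcmc=mcmc or {})
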