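"""Synthetic multi-center registries and the classification benchmark.

Scenarios emulate a national disease register: m centers of heterogeneous
size (log-normal with a floor, so very small centers occur), patient
covariates that influence both center membership (differential case-mix)
and outcome (confounding), and true center effects on the logit scale with
designated low- and high-risk centers relative to the clinical tolerance.
The default scenario is calibrated to a register of 2355 patients across 63
centers with a 22% marginal event rate and true class shares of 30% low /
22% high.

``run_benchmark`` measures, per estimation method, the power and type I
error of the three-way low/accepted/high classification, the coverage of
95% intervals for the true potential full-population risk, and the fraction
of correct classifications.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .classification import ClassificationConfig, classify, population_risk
from .outcome_models import fit_fe_logistic, fit_me_clustered, fit_me_normal
from .registry_io import Registry, registry_from_frame
from .standardization import direct_risk, dr_risk
from .propensity import fit_ps_multinomial, fit_ps_per_center

__all__ = [
    "Scenario",
    "Truth",
    "BenchResult",
    "resolve_truth",
    "true_potential_risks",
    "generate_registry",
    "run_benchmark",
]

METHODS = ("fe_ml", "fe_firth", "me_normal", "me_clustered", "dr_ps")


@dataclass
class Scenario:
    """Generative design for a synthetic multi-center registry.

    Covariates are independent standard normal; center membership follows a
    softmax model with log-size intercepts and per-center covariate slopes
    of magnitude ``confounding_strength``; outcomes are Bernoulli with
    logit  L' beta_true (+ optional centered quadratic term in the first
    covariate) + psi_c.  ``psi_model`` is ``mixture`` (three classes at
    configurable risk ratios relative to the population risk), ``normal``
    (exchangeable effects), or ``fixed`` (user-supplied vector).
    """

    m: int = 63
    n_total: int = 2355
    target_event_rate: float = 0.22
    n_covariates: int = 2
    beta_true: tuple[float, ...] = (0.7, 0.4)
    confounding_strength: float = 0.5
    size_sigma: float = 1.0               # log-normal sd of center sizes
    min_size: int = 5
    psi_model: str = "mixture"            # mixture | normal | fixed
    share_low: float = 0.30
    share_high: float = 0.22
    risk_ratio_low: float = 0.70          # true E{Y(c)} target / E(Y) for low class
    risk_ratio_high: float = 1.35
    psi_jitter_sd: float = 0.05           # within-class logit jitter
    psi_sd: float = 0.4                   # for psi_model == "normal"
    psi_fixed: tuple[float, ...] | None = None
    outcome_quadratic: float = 0.0        # coefficient on (x1^2 - 1) in the outcome truth
    assignment_quadratic: float = 0.0     # coefficient scale on (x1^2 - 1) in assignment
    omit_covariate_from_outcome: bool = False   # analysis outcome model drops x1_sq
    omit_covariate_from_ps: bool = False        # analysis PS model drops x1_sq
    lam: float = 0.20
    k: float = 0.75
    K_clusters: int = 3
    seed: int = 12345

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need m >= 2 centers")
        if not 0 < self.target_event_rate < 1:
            raise ValueError("event rate must lie in (0,1)")
        if len(self.beta_true) != self.n_covariates:
            raise ValueError("beta_true length must equal n_covariates")

    @classmethod
    def from_json(cls, path) -> "Scenario":
        with open(path) as fh:
            raw = json.load(fh)
        raw.pop("name", None)
        if "beta_true" in raw:
            raw["beta_true"] = tuple(raw["beta_true"])
        if raw.get("psi_fixed") is not None:
            raw["psi_fixed"] = tuple(raw["psi_fixed"])
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class Truth:
    """Resolved generative truth for one scenario."""

    psi_true: np.ndarray            # (m,)
    size_targets: np.ndarray        # expected n_c
    assign_intercepts: np.ndarray   # (m,)
    assign_slopes: np.ndarray       # (m, p)
    assign_quad: np.ndarray         # (m,)
    true_risks: np.ndarray          # E{Y(c)} per center
    true_event_rate: float          # marginal E(Y)
    true_classes: list[str]
    centers: list[str]


def _gh_grid(scenario: Scenario, n_nodes: int = 64):
    """Quadrature nodes/weights for the marginal law of the outcome logit."""
    beta = np.asarray(scenario.beta_true, dtype=float)
    bq = scenario.outcome_quadratic
    x, wx = np.polynomial.hermite_e.hermegauss(n_nodes)
    wx = wx / wx.sum()
    if bq == 0.0:
        sigma = float(np.sqrt(beta @ beta))
        return sigma * x, wx
    # quadratic in x1: tensor grid over x1 and the remaining normal part
    s2 = float(np.sqrt(beta[1:] @ beta[1:])) if len(beta) > 1 else 0.0
    if s2 == 0.0:
        eta = beta[0] * x + bq * (x**2 - 1)
        return eta, wx
    eta = (
        (beta[0] * x + bq * (x**2 - 1))[:, None] + s2 * x[None, :]
    ).ravel()
    w = (wx[:, None] * wx[None, :]).ravel()
    return eta, w


def _expected_risk(eta_nodes, w_nodes, psi: float) -> float:
    return float(w_nodes @ expit(eta_nodes + psi))


def resolve_truth(scenario: Scenario, n_cal: int = 200_000) -> Truth:
    """Resolve the scenario's generative parameters deterministically.

    The base center effect is calibrated by Monte Carlo so the marginal
    event rate matches the target; for the mixture model the low/high class
    offsets are then solved by quadrature so the class-mean true potential
    risks sit at the configured risk ratios.  Deterministic given
    ``scenario.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 7]))
    m, p = scenario.m, scenario.n_covariates
    beta = np.asarray(scenario.beta_true, dtype=float)

    # structural randomness
    n_low = int(round(scenario.share_low * m))
    n_high = int(round(scenario.share_high * m))
    jitter = scenario.psi_jitter_sd * rng.standard_normal(m)
    slopes = scenario.confounding_strength * rng.standard_normal((m, p))
    quad_slopes = scenario.assignment_quadratic * rng.standard_normal(m)
    raw = rng.lognormal(0.0, scenario.size_sigma, m)
    targets = raw / raw.sum() * scenario.n_total
    targets = np.maximum(targets, scenario.min_size)
    targets = targets / targets.sum() * scenario.n_total
    a = np.log(targets / scenario.n_total)

    # class designations, spread evenly across the size distribution so the
    # size-weighted class mix matches the nominal shares (keeps the marginal
    # event rate on target under heavy size heterogeneity)
    shares = {"low": n_low, "high": n_high, "accepted": m - n_low - n_high}
    assigned = {c: 0 for c in shares}
    cls = np.empty(m, dtype=object)
    for rank, center in enumerate(np.argsort(targets)):
        pick = max(
            (c for c in shares if shares[c] > 0),
            key=lambda c: shares[c] / max(shares[c] + assigned[c], 1)
            + 1e-9 * rng.random(),
        )
        cls[center] = pick
        shares[pick] -= 1
        assigned[pick] += 1

    # calibration sample for the marginal event rate
    cal_rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 11]))
    L = cal_rng.standard_normal((n_cal, p))
    qcol = L[:, 0] ** 2 - 1.0
    logits = a[None, :] + L @ slopes.T + qcol[:, None] * quad_slopes[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    pr = np.exp(logits)
    pr /= pr.sum(axis=1, keepdims=True)
    u = cal_rng.random(n_cal)[:, None]
    C = (u > np.cumsum(pr, axis=1)).sum(axis=1)
    eta_base = L @ beta + scenario.outcome_quadratic * qcol

    eta_nodes, w_nodes = _gh_grid(scenario)
    target = scenario.target_event_rate

    if scenario.psi_model == "fixed":
        if scenario.psi_fixed is None or len(scenario.psi_fixed) != m:
            raise ValueError("psi_fixed must supply m values")
        psi = np.asarray(scenario.psi_fixed, dtype=float)
    elif scenario.psi_model == "normal":
        psi_dev = scenario.psi_sd * rng.standard_normal(m)
        t = brentq(
            lambda t0: float(np.mean(expit(eta_base + psi_dev[C] + t0))) - target,
            -15, 15,
        )
        psi = psi_dev + t
    else:
        # mixture: anchor each class's mean potential risk at its configured
        # ratio of the target rate (solved by quadrature; the realized
        # marginal rate then lands close to the target because class
        # designations are size-balanced)
        level = {}
        for name, ratio in (
            ("low", scenario.risk_ratio_low),
            ("accepted", 1.0),
            ("high", scenario.risk_ratio_high),
        ):
            goal = min(max(ratio * target, 1e-4), 1 - 1e-4)
            level[name] = brentq(
                lambda s: _expected_risk(eta_nodes, w_nodes, s) - goal, -15, 15
            )
        psi = np.array([level[c] for c in cls]) + jitter

    true_risks = np.array([_expected_risk(eta_nodes, w_nodes, s) for s in psi])
    ey = float(np.mean(expit(eta_base + psi[C])))
    lo, hi = (1 - scenario.lam) * ey, (1 + scenario.lam) * ey
    true_classes = [
        "low" if r < lo else ("high" if r > hi else "accepted") for r in true_risks
    ]
    centers = [f"c{i+1:02d}" for i in range(m)]
    return Truth(
        psi_true=psi,
        size_targets=targets,
        assign_intercepts=a,
        assign_slopes=slopes,
        assign_quad=quad_slopes,
        true_risks=true_risks,
        true_event_rate=ey,
        true_classes=true_classes,
        centers=centers,
    )


def true_potential_risks(
    scenario: Scenario, mc_draws: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """True E{Y(c)} per center with the implied three-way class.

    Uses Gauss-Hermite quadrature over the marginal covariate law; pass
    ``mc_draws`` to cross-check by plain Monte Carlo instead.
    """
    truth = resolve_truth(scenario)
    risks = truth.true_risks
    if mc_draws is not None:
        rng = np.random.default_rng(seed)
        L = rng.standard_normal((mc_draws, scenario.n_covariates))
        eta = L @ np.asarray(scenario.beta_true) + scenario.outcome_quadratic * (
            L[:, 0] ** 2 - 1.0
        )
        risks = np.array([float(np.mean(expit(eta + s))) for s in truth.psi_true])
    return pd.DataFrame(
        {
            "center": truth.centers,
            "psi_true": truth.psi_true,
            "true_risk": risks,
            "true_class": truth.true_classes,
        }
    ).set_index("center")


def generate_registry(
    scenario: Scenario, seed, truth: Truth | None = None
) -> Registry:
    """Draw one patient-level registry from the scenario's generative law.

    Bit-for-bit reproducible for a fixed seed.  If a center draws zero
    patients, center membership is redrawn (up to 20 attempts), then one
    random patient is reassigned to each still-empty center, with a warning.
    When the scenario has any quadratic term the registry carries the
    centered square of the first covariate as column ``x1_sq`` so both the
    correct and the deliberately misspecified analysis models can be fit.
    """
    truth = truth or resolve_truth(scenario)
    rng = np.random.default_rng(seed)
    n, p, m = scenario.n_total, scenario.n_covariates, scenario.m
    L = rng.standard_normal((n, p))
    qcol = L[:, 0] ** 2 - 1.0
    logits = (
        truth.assign_intercepts[None, :]
        + L @ truth.assign_slopes.T
        + qcol[:, None] * truth.assign_quad[None, :]
    )
    logits -= logits.max(axis=1, keepdims=True)
    pr = np.exp(logits)
    pr /= pr.sum(axis=1, keepdims=True)
    cum = np.cumsum(pr, axis=1)
    C = (rng.random(n)[:, None] > cum).sum(axis=1)
    for _ in range(20):
        if np.bincount(C, minlength=m).min() > 0:
            break
        C = (rng.random(n)[:, None] > cum).sum(axis=1)
    counts = np.bincount(C, minlength=m)
    if counts.min() == 0:
        empties = np.flatnonzero(counts == 0)
        warnings.warn(
            f"{len(empties)} center(s) drew no patients; reassigning one "
            f"random patient each"
        )
        for c in empties:
            donors = np.flatnonzero(np.bincount(C, minlength=m)[C] > 1)
            C[rng.choice(donors)] = c
    eta = L @ np.asarray(scenario.beta_true) + scenario.outcome_quadratic * qcol
    eta = eta + truth.psi_true[C]
    Y = (rng.random(n) < expit(eta)).astype(np.int8)

    cols = {f"x{j+1}": L[:, j] for j in range(p)}
    covs = list(cols)
    if scenario.outcome_quadratic != 0.0 or scenario.assignment_quadratic != 0.0:
        cols["x1_sq"] = qcol
        covs.append("x1_sq")
    df = pd.DataFrame(
        {"outcome": Y, "center": [truth.centers[c] for c in C], **cols}
    )
    # keep the center index in canonical order regardless of draw order
    df = df.sort_values("center", kind="stable").reset_index(drop=True)
    return registry_from_frame(df, covariates=covs)


@dataclass
class BenchResult:
    """Operating characteristics of center classification per method."""

    summary: pd.DataFrame           # rows: methods, columns: rates (in %)
    mc_se: pd.DataFrame             # matching Monte Carlo standard errors (in %)
    per_center: pd.DataFrame        # per-center correct-classification curve
    n_reps: int
    failures: dict[str, int]

    def to_json(self, path) -> None:
        payload = {
            "n_reps": self.n_reps,
            "failures": self.failures,
            "summary": self.summary.to_dict(),
            "mc_se": self.mc_se.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


_LEAN_MCMC = {"chains": 2, "warmup": 400, "draws": 400, "rhat_threshold": 1.05}


def _analysis_views(reg: Registry, scenario: Scenario) -> tuple[Registry, Registry]:
    """(outcome-model registry, PS-model registry) honoring the
    misspecification switches: the generating truth keeps the quadratic
    term, the flagged analysis model drops it."""
    out_reg = ps_reg = reg
    if scenario.omit_covariate_from_outcome and "x1_sq" in reg.covariate_cols:
        out_reg = reg.with_covariates(
            [c for c in reg.covariate_cols if c != "x1_sq"]
        )
    if scenario.omit_covariate_from_ps and "x1_sq" in reg.covariate_cols:
        ps_reg = reg.with_covariates(
            [c for c in reg.covariate_cols if c != "x1_sq"]
        )
    return out_reg, ps_reg


def _fit_and_standardize(method, reg, scenario, rep_seed, mcmc_budget):
    out_reg, ps_reg = _analysis_views(reg, scenario)
    if method == "fe_ml":
        fit = fit_fe_logistic(out_reg, firth=False)
        if not fit.converged:
            raise RuntimeError("no convergence")
        return direct_risk(fit, out_reg)
    if method == "fe_firth":
        fit = fit_fe_logistic(out_reg, firth=True)
        return direct_risk(fit, out_reg)
    if method == "me_normal":
        cfg = {**_LEAN_MCMC, **(mcmc_budget or {}), "seed": rep_seed}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_me_normal(out_reg, mcmc=cfg)
        return direct_risk(fit, out_reg)
    if method == "me_clustered":
        cfg = {**_LEAN_MCMC, **(mcmc_budget or {}), "seed": rep_seed}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_me_clustered(out_reg, K=scenario.K_clusters, mcmc=cfg)
        return direct_risk(fit, out_reg)
    if method == "dr_ps":
        psfit = (
            fit_ps_multinomial(ps_reg) if reg.m <= 10 else fit_ps_per_center(ps_reg)
        )
        return dr_risk(out_reg, psfit, firth=True)
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(
    scenario: Scenario,
    methods=("fe_firth", "me_normal"),
    n_reps: int = 200,
    seed: int = 0,
    mcmc_budget: dict | None = None,
) -> BenchResult:
    """Monte Carlo benchmark of classification operating characteristics.

    Per replicate: generate a registry, fit each method, standardize,
    classify with the scenario's (lambda, k), and compare against the true
    classes implied by the generative law.  Replicates where a method fails
    are excluded from that method's denominator and counted in
    ``failures``.  Rates are reported in percent with replicate-level Monte
    Carlo standard errors.
    """
    for mth in methods:
        if mth not in METHODS:
            raise ValueError(f"unknown method {mth!r}")
    truth = resolve_truth(scenario)
    tclass = np.array(truth.true_classes)
    config = ClassificationConfig(lam=scenario.lam, k=scenario.k)
    z95 = 1.959963984540054

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    per_rep: dict[str, list[dict]] = {mth: [] for mth in methods}
    correct_counts = {mth: np.zeros(scenario.m) for mth in methods}
    correct_trials = {mth: np.zeros(scenario.m) for mth in methods}
    failures = {mth: 0 for mth in methods}

    for r, child in enumerate(children):
        reg = generate_registry(scenario, child, truth)
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        pr = population_risk(reg)
        for mth in methods:
            try:
                ests = _fit_and_standardize(mth, reg, scenario, rep_seed, mcmc_budget)
            except Exception:
                failures[mth] += 1
                continue
            est = np.array([e.estimate for e in ests])
            sd = np.array([e.sd for e in ests])
            labels = np.array([l.label for l in classify(ests, pr, config)])
            cover = (est - z95 * sd <= truth.true_risks) & (
                truth.true_risks <= est + z95 * sd
            )
            rec = {}
            for tgt in ("low", "high"):
                sel = tclass == tgt
                rec[f"power_detect_{tgt}"] = (
                    float(np.mean(labels[sel] == tgt)) if sel.any() else np.nan
                )
            pairs = [
                ("typeI_low_as_high", "low", "high"),
                ("typeI_accepted_as_high", "accepted", "high"),
                ("typeI_high_as_low", "high", "low"),
                ("typeI_accepted_as_low", "accepted", "low"),
            ]
            for key, true_c, lab_c in pairs:
                sel = tclass == true_c
                rec[key] = (
                    float(np.mean(labels[sel] == lab_c)) if sel.any() else np.nan
                )
            rec["ci_coverage_for_potential_risk"] = float(cover.mean())
            rec["pct_classified_high"] = float(np.mean(labels == "high"))
            rec["pct_classified_low"] = float(np.mean(labels == "low"))
            rec["pct_correct_three_way"] = float(np.mean(labels == tclass))
            per_rep[mth].append(rec)
            correct_counts[mth] += labels == tclass
            correct_trials[mth] += 1

    keys = [
        "power_detect_high", "power_detect_low",
        "typeI_low_as_high", "typeI_accepted_as_high",
        "typeI_high_as_low", "typeI_accepted_as_low",
        "ci_coverage_for_potential_risk",
        "pct_classified_high", "pct_classified_low", "pct_correct_three_way",
    ]
    summary = {}
    mcse = {}
    for mth in methods:
        frame = pd.DataFrame(per_rep[mth])
        if frame.empty:
            summary[mth] = {k: np.nan for k in keys}
            mcse[mth] = {k: np.nan for k in keys}
            continue
        summary[mth] = {k: 100 * float(frame[k].mean()) for k in keys}
        mcse[mth] = {
            k: 100 * float(frame[k].std(ddof=1) / np.sqrt(frame[k].notna().sum()))
            for k in keys
        }
    per_center = pd.DataFrame(
        {
            "center": truth.centers,
            "true_risk": truth.true_risks,
            "true_class": truth.true_classes,
            **{
                f"correct_{mth}": correct_counts[mth]
                / np.maximum(correct_trials[mth], 1)
                for mth in methods
            },
        }
    ).set_index("center")
    return BenchResult(
        summary=pd.DataFrame(summary).T[keys],
        mc_se=pd.DataFrame(mcse).T[keys],
        per_center=per_center,
        n_reps=n_reps,
        failures=failures,
    )
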