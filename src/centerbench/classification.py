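"""Clinical-tolerance classification of centers as low / accepted / high.

A center is flagged only when the data carry sufficient statistical
evidence (normal percentile z_k) that its potential full-population risk
departs from the population risk E(Y) by more than a clinical tolerance
fraction lambda:

    low  iff  estimate + z_k * sd < (1 - lambda) E(Y)
    high iff  (1 + lambda) E(Y) < estimate - z_k * sd

with strict inequalities, so threshold ties resolve to "accepted".  With
lambda = 0 and k = 0.975 the rule reduces to the classical criterion that
the 95% confidence interval excludes the population risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

from .registry_io import Registry
from .standardization import StandardizedEstimate

__all__ = ["ClassificationConfig", "CenterLabel", "population_risk", "classify",
           "labels_frame"]


@dataclass
class ClassificationConfig:
    """Tolerance lambda, evidence level k, and the population-risk source."""

    lam: float = 0.20
    k: float = 0.75
    population_risk_source: str = "sample_mean"   # or "external"

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("tolerance lambda must be >= 0")
        if not 0.5 < self.k < 1:
            raise ValueError("evidence level k must lie in (0.5, 1)")

    @property
    def z_k(self) -> float:
        return float(norm.ppf(self.k))


@dataclass
class CenterLabel:
    center_id: str
    label: str                    # "low" | "accepted" | "high"
    estimate: float
    sd: float
    population_risk: float
    lower_threshold: float        # (1 - lambda) E(Y)
    upper_threshold: float        # (1 + lambda) E(Y)


def population_risk(source: Registry | float) -> float:
    """Population average risk E(Y): sample mean of outcomes, or an
    external benchmark value passed through unchanged."""
    if isinstance(source, Registry):
        if source.n == 0:
            raise ValueError("empty registry")
        return float(source.y.mean())
    value = float(source)
    if not 0.0 <= value <= 1.0:
        raise ValueError("external benchmark must lie in [0,1]")
    return value


def classify(
    estimates: list[StandardizedEstimate],
    pop_risk: float,
    config: ClassificationConfig | None = None,
) -> list[CenterLabel]:
    """Label each center low / accepted / high under the tolerance criterion."""
    config = config or ClassificationConfig()
    if config.lam > 0 and not 0.0 < pop_risk < 1.0:
        raise ValueError(
            f"population risk {pop_risk} outside (0,1) with lambda > 0"
        )
    z = config.z_k
    lo_thr = (1.0 - config.lam) * pop_risk
    hi_thr = (1.0 + config.lam) * pop_risk
    out = []
    for e in estimates:
        if e.sd < 0:
            raise ValueError("negative sd")
        if e.estimate + z * e.sd < lo_thr:
            label = "low"
        elif hi_thr < e.estimate - z * e.sd:
            label = "high"
        else:
            label = "accepted"
        out.append(
            CenterLabel(
                center_id=e.center_id,
                label=label,
                estimate=e.estimate,
                sd=e.sd,
                population_risk=pop_risk,
                lower_threshold=lo_thr,
                upper_threshold=hi_thr,
            )
        )
    return out


def labels_frame(labels: list[CenterLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "center": [l.center_id for l in labels],
            "label": [l.label for l in labels],
            "estimate": [l.estimate for l in labels],
            "sd": [l.sd for l in labels],
            "population_risk": [l.population_risk for l in labels],
            "lower_threshold": [l.lower_threshold for l in labels],
            "upper_threshold": [l.upper_threshold for l in labels],
        }
    )
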