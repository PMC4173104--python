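"""Report generation: summary tables and the two standard profiling plots.

Plots are artifacts only; every number they show is also written as CSV so
downstream checks never need to parse images.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.stats import norm

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .classification import CenterLabel, labels_frame
from .registry_io import Registry
from .standardization import StandardizedEstimate, estimates_frame

__all__ = ["render_report"]

_COLORS = {"low": "#2166ac", "accepted": "#7f7f7f", "high": "#b2182b"}


def render_report(
    estimates: list[StandardizedEstimate],
    labels: list[CenterLabel],
    registry: Registry,
    out_dir,
    interval_level: float = 0.50,
) -> dict[str, str]:
    """Write the summary table, observed-vs-standardized scatter and
    caterpillar plot of the per-center potential full-population risk.

    The caterpillar intervals are estimate +/- z * sd at ``interval_level``
    (z the (1+level)/2 normal percentile); vertical lines mark the clinical
    decision limits (1-lambda)E(Y) and (1+lambda)E(Y).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if [e.center_id for e in estimates] != [l.center_id for l in labels]:
        raise ValueError("estimates and labels must share the center index")

    est = estimates_frame(estimates)
    lab = labels_frame(labels)
    observed = registry.observed_risks()
    sizes = registry.center_sizes
    order = {c: i for i, c in enumerate(registry.centers)}
    est = est.assign(
        observed_risk=[observed[order[c]] for c in est["center"]],
        n_c=[int(sizes[order[c]]) for c in est["center"]],
        label=lab["label"].to_numpy(),
    )
    summary_path = out_dir / "summary.csv"
    est.to_csv(summary_path, index=False)

    z = float(norm.ppf(0.5 + interval_level / 2))
    lo_thr = labels[0].lower_threshold
    hi_thr = labels[0].upper_threshold

    # observed vs standardized scatter, colored by label
    fig, ax = plt.subplots(figsize=(5.5, 5))
    for name in ("accepted", "low", "high"):
        sel = est["label"] == name
        if sel.any():
            ax.scatter(
                est.loc[sel, "observed_risk"],
                est.loc[sel, "estimate"],
                s=18,
                c=_COLORS[name],
                label=name,
            )
    lim = [0, max(est["observed_risk"].max(), est["estimate"].max()) * 1.1]
    ax.plot(lim, lim, lw=0.5, c="k")
    ax.set_xlabel("observed center-specific risk")
    ax.set_ylabel("potential full-population risk")
    ax.legend(frameon=False)
    scatter_path = out_dir / "observed_vs_standardized.png"
    fig.tight_layout()
    fig.savefig(scatter_path, dpi=120)
    plt.close(fig)

    # caterpillar plot
    srt = est.sort_values("estimate").reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, max(3.0, 0.12 * len(srt))))
    yy = np.arange(len(srt))
    ax.errorbar(
        srt["estimate"], yy, xerr=z * srt["sd"], fmt="o", ms=3,
        ecolor="#999999", elinewidth=1,
        color="k", zorder=2,
    )
    for name in ("low", "high"):
        sel = srt["label"] == name
        ax.scatter(srt.loc[sel, "estimate"], yy[sel], c=_COLORS[name], s=22, zorder=3)
    ax.axvline(lo_thr, color="gray", lw=1)
    ax.axvline(hi_thr, color="gray", lw=1)
    ax.set_yticks(yy)
    ax.set_yticklabels(srt["center"], fontsize=5)
    ax.set_xlabel(
        f"potential full-population risk with {interval_level:.0%} interval"
    )
    cat_path = out_dir / "caterpillar.png"
    fig.tight_layout()
    fig.savefig(cat_path, dpi=120)
    plt.close(fig)

    interval_csv = out_dir / "intervals.csv"
    srt.assign(
        half_width=z * srt["sd"],
        lower=srt["estimate"] - z * srt["sd"],
        upper=srt["estimate"] + z * srt["sd"],
    ).to_csv(interval_csv, index=False)
    return {
        "summary": str(summary_path),
        "scatter": str(scatter_path),
        "caterpillar": str(cat_path),
        "intervals": str(interval_csv),
    }
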