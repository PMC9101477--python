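"""Optional figure helpers (requires matplotlib, installed via the
``plot`` extra). Numbers, not figures, are the tested surface; these
render the ratio-curve/breakpoint and KM-comparison views of a result."""

from __future__ import annotations

import numpy as np

from .curve_break import BreakpointResult
from .curves import RatioCurve
from .survival import SurvivalSummary

__all__ = ["plot_ratio_curve", "plot_km_comparison"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_ratio_curve(curve: RatioCurve, breakpoint: BreakpointResult | None = None, ax=None):
    """Per-count ratio curve with CI band, optionally the estimated break."""
    ax = _ax(ax)
    ax.plot(curve.levels, curve.ratio, "o-", ms=3, label=curve.scale)
    ax.fill_between(curve.levels, curve.ci_low, curve.ci_high, alpha=0.2)
    if breakpoint is not None:
        ax.axvline(breakpoint.k_hat, color="crimson", ls="--",
                   label=f"cutoff = {breakpoint.k_hat:g}")
        ys = breakpoint.provenance.get("y_smooth")
        if ys is not None:
            ax.plot(curve.levels, np.exp(ys), color="gray", lw=1, label="LOWESS")
    ax.axhline(1.0, color="k", lw=0.5)
    ax.set_xlabel("examined lymph nodes")
    ax.set_ylabel(curve.scale.replace("-", " "))
    ax.legend(frameon=False)
    return ax


def plot_km_comparison(above: SurvivalSummary, below: SurvivalSummary, ax=None):
    """Step KM curves for the two sides of a cutoff split."""
    ax = _ax(ax)
    for s in (above, below):
        ax.step(s.curve["time"], s.curve["surv"], where="post", label=s.label)
        ax.fill_between(s.curve["time"], s.curve["ci_low"], s.curve["ci_high"],
                        step="post", alpha=0.15)
    ax.set_xlabel("months")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    return ax
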