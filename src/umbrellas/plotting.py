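"""Umbrella and power plots (matplotlib, mean on x and SD on y)."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe default; no-op under a GUI
import matplotlib.pyplot as plt
import pandas as pd

from .scales import DiscretePoint, RatingScale, outline

__all__ = ["umbrella_plot", "power_curve_plot"]


def umbrella_plot(
    scale: RatingScale,
    points: Sequence[DiscretePoint] | pd.DataFrame | None = None,
    grid_step: float = 0.01,
    ax: "plt.Axes | None" = None,
) -> "plt.Axes":
    """Draw the continuous umbrella outline, optionally with (mean, SD) points.

    ``points`` may be DiscretePoints (e.g. from enumeration) or a DataFrame
    with ``mean`` and a SD column (``sd`` or ``sd_pop``).  SDs are expected in
    the population convention, matching the outline.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    frame = outline(scale, grid_step).to_frame()
    ax.plot(frame["mean"], frame["s_max"], color="black", lw=1.2)
    ax.plot(frame["mean"], frame["s_min"], color="black", lw=1.2)
    if points is not None:
        if isinstance(points, pd.DataFrame):
            sd_col = "sd" if "sd" in points.columns else "sd_pop"
            ax.scatter(points["mean"], points[sd_col], s=12, alpha=0.7, zorder=3)
        else:
            ax.scatter(
                [p.mean for p in points],
                [p.sd for p in points],
                s=12,
                alpha=0.7,
                zorder=3,
            )
    ax.set_xlabel("mean")
    ax.set_ylabel("standard deviation (n denominator)")
    ax.set_xlim(scale.x_min - 0.2, scale.x_max + 0.2)
    ax.set_ylim(0, scale.k / 2 * 1.08)
    return ax


def power_curve_plot(
    curve: pd.DataFrame, ax: "plt.Axes | None" = None
) -> "plt.Axes":
    """Plot min/max nominal power against total sample size."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["n_total"], curve["min_power"], marker="o", label="min power")
    if "max_power" in curve.columns:
        ax.plot(curve["n_total"], curve["max_power"], marker="s", label="max power")
    ax.set_xlabel("combined sample size")
    ax.set_ylabel("nominal power")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
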