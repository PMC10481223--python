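"""Chart plotting: the normative percentile chart and individual overlays."""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .reference import ReferenceChart

_STYLES = {15: "-", 50: "--", 85: "-."}


def plot_reference_chart(chart: ReferenceChart, ax=None, max_day: float = 60.0):
    """Plot MM% percentile lines vs day postpartum (15 solid / 50 dashed / 85 dash-dot)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    mids = np.array(
        [
            (b.start + min(b.end, max_day)) / 2.0 if not math.isinf(b.end) else max_day
            for b in chart.bins
        ]
    )
    keep = mids <= max_day
    for j, lev in enumerate(chart.levels):
        vals = chart.values[:, j]
        style = _STYLES.get(lev, ":")
        ax.plot(mids[keep], vals[keep], style, color="black", label=f"p{lev}")
    ax.set_xlabel("day postpartum")
    ax.set_ylabel("MM%")
    ax.set_ylim(0, 105)
    ax.legend()
    return ax


def plot_scans_over_chart(df, chart: ReferenceChart, ax=None, max_day: float = 60.0):
    """Scatter scans (coloured by class when available) over the percentile lines."""
    ax = plot_reference_chart(chart, ax=ax, max_day=max_day)
    sub = df[df["day_postpartum"] <= max_day]
    if "class_label" in sub.columns:
        for lab, grp in sub.groupby("class_label"):
            ax.scatter(grp["day_postpartum"], grp["mm_percent"], s=8, alpha=0.5, label=lab)
        ax.legend()
    else:
        ax.scatter(sub["day_postpartum"], sub["mm_percent"], s=8, alpha=0.5)
    return ax
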