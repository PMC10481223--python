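"""Group separation and threshold performance.

Quantifies how well the day-matched 15th-percentile line separates
breastfeeding classes: below-threshold sensitivity/specificity inside a
day-postpartum window, per-day-range group means with a two-factor ANOVA
(class x day range) and Tukey HSD post-hoc comparisons, and a per-day moving
median for trajectory-style plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import UndefinedSensitivityError, ValidationError
from .reference import BELOW, NO_REFERENCE, DayBin, ReferenceChart, flag_frame

DEFAULT_DAY_WINDOW = (6.0, 21.0)  # day range "6-20", half-open [6, 21)


def display_percent(value: float) -> int:
    """Round a percentage for display (half away from zero)."""
    return int(np.floor(value + 0.5))


def sensitivity_from_counts(n_below: int, n_positive: int) -> float:
    """Below-threshold sensitivity in percent from raw counts."""
    if n_positive <= 0:
        raise UndefinedSensitivityError("no positive-class records in window")
    if not 0 <= n_below <= n_positive:
        raise ValidationError(f"inconsistent counts: {n_below} below of {n_positive}")
    return 100.0 * n_below / n_positive


@dataclass(frozen=True)
class ThresholdEvaluation:
    """Counts and rates for the below-threshold screening rule.

    ``sensitivity``/``specificity`` are stored at full precision;
    ``sensitivity_display`` is the nearest-integer percent used in reports.
    """

    day_window: tuple
    level: int
    positive_class: str
    reference_class: str
    n_positive: int
    n_below: int
    sensitivity: float
    n_reference: int
    n_ref_below: int
    specificity: float | None
    n_no_reference: int = 0

    @property
    def sensitivity_display(self) -> int:
        return display_percent(self.sensitivity)

    def to_dict(self) -> dict:
        return {
            "day_window": list(self.day_window),
            "percentile_level": self.level,
            "positive_class": self.positive_class,
            "reference_class": self.reference_class,
            "n_positive": self.n_positive,
            "n_below": self.n_below,
            "sensitivity_percent": self.sensitivity,
            "sensitivity_percent_display": self.sensitivity_display,
            "n_reference": self.n_reference,
            "n_ref_below": self.n_ref_below,
            "specificity_percent": self.specificity,
            "n_no_reference_excluded": self.n_no_reference,
        }


def evaluate_threshold(
    df: pd.DataFrame,
    chart: ReferenceChart,
    *,
    positive_class: str = "low_supply",
    reference_class: str = "normal",
    day_window: tuple = DEFAULT_DAY_WINDOW,
    level: int = 15,
) -> ThresholdEvaluation:
    """Sensitivity/specificity of the below-threshold flag in a day window.

    ``df`` must carry day_postpartum, mm_percent and class_label columns.
    Records without a usable reference bin are excluded from numerator and
    denominator alike, and their count is reported.
    """
    lo, hi = day_window
    sub = df[(df["day_postpartum"] >= lo) & (df["day_postpartum"] < hi)].copy()
    sub["flag"] = flag_frame(sub, chart, level=level)
    no_ref = int((sub["flag"] == NO_REFERENCE).sum())
    sub = sub[sub["flag"] != NO_REFERENCE]

    pos = sub[sub["class_label"] == positive_class]
    if len(pos) == 0:
        raise UndefinedSensitivityError(
            f"no {positive_class!r} records with reference in window [{lo}, {hi})"
        )
    n_below = int((pos["flag"] == BELOW).sum())
    sens = sensitivity_from_counts(n_below, len(pos))

    ref = sub[sub["class_label"] == reference_class]
    n_ref_below = int((ref["flag"] == BELOW).sum())
    spec = 100.0 * (1.0 - n_ref_below / len(ref)) if len(ref) else None

    return ThresholdEvaluation(
        day_window=(lo, hi),
        level=level,
        positive_class=positive_class,
        reference_class=reference_class,
        n_positive=len(pos),
        n_below=n_below,
        sensitivity=sens,
        n_reference=len(ref),
        n_ref_below=n_ref_below,
        specificity=spec,
        n_no_reference=no_ref,
    )


DEFAULT_DAY_RANGES = (
    DayBin(0.0, 5.0),
    DayBin(5.0, 10.0),
    DayBin(10.0, 15.0),
    DayBin(15.0, 21.0),
    DayBin(21.0, 60.0),
)


@dataclass(frozen=True)
class GroupComparison:
    """Tidy per-cell statistics plus ANOVA and per-range Tukey results."""

    cells: pd.DataFrame  # class_label, day_range, n, mean, se
    anova: pd.DataFrame  # statsmodels anova_lm table
    anova_p_class: float
    anova_p_interaction: float | None
    tukey: pd.DataFrame  # per-range pairwise comparisons
    dropped_ranges: tuple = ()


def compare_groups(
    df: pd.DataFrame,
    day_ranges=DEFAULT_DAY_RANGES,
    classes=("normal", "low_supply"),
) -> GroupComparison:
    """Two-factor comparison of MM% by class and day range.

    Fixed-effects two-way ANOVA (class x day range) on all cells with data,
    followed by Tukey HSD on the class factor within each day range (the
    interaction-style post-hoc).  Ranges with an empty or singleton cell for
    any class are dropped with a warning.
    """
    classes = list(classes)
    if len(classes) < 2:
        raise ValidationError("compare_groups needs at least two classes")
    df = df[df["class_label"].isin(classes)]

    kept, dropped = [], []
    for rng in day_ranges:
        sub = df[(df["day_postpartum"] >= rng.start) & (df["day_postpartum"] < rng.end)]
        sizes = sub.groupby("class_label").size()
        if all(sizes.get(c, 0) >= 2 for c in classes):
            kept.append(rng)
        else:
            dropped.append(rng)
            warnings.warn(f"day range {rng.label()} dropped: empty/singleton cell", stacklevel=2)
    if not kept:
        raise ValidationError("no day range has >= 2 records per class")

    parts = []
    for rng in kept:
        sub = df[(df["day_postpartum"] >= rng.start) & (df["day_postpartum"] < rng.end)].copy()
        sub["day_range"] = rng.label()
        parts.append(sub)
    data = pd.concat(parts, ignore_index=True)

    cells = (
        data.groupby(["class_label", "day_range"])["mm_percent"]
        .agg(n="size", mean="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
        .reset_index()
    )

    if len(kept) >= 2:
        model = smf.ols("mm_percent ~ C(class_label) * C(day_range)", data=data).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        p_class = float(anova.loc["C(class_label)", "PR(>F)"])
        p_inter = float(anova.loc["C(class_label):C(day_range)", "PR(>F)"])
    else:
        model = smf.ols("mm_percent ~ C(class_label)", data=data).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        p_class = float(anova.loc["C(class_label)", "PR(>F)"])
        p_inter = None

    tukey_rows = []
    for rng in kept:
        sub = data[data["day_range"] == rng.label()]
        res = pairwise_tukeyhsd(sub["mm_percent"], sub["class_label"])
        tbl = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        tbl.insert(0, "day_range", rng.label())
        tukey_rows.append(tbl)
    tukey = pd.concat(tukey_rows, ignore_index=True)

    return GroupComparison(
        cells=cells,
        anova=anova,
        anova_p_class=p_class,
        anova_p_interaction=p_inter,
        tukey=tukey,
        dropped_ranges=tuple(dropped),
    )


def moving_median(
    df: pd.DataFrame,
    class_label: str,
    window_days: float = 2.0,
    days=range(0, 21),
) -> pd.Series:
    """Per-day moving median of MM% for one class.

    For each integer day d, the median of class records with day_postpartum
    in [d - window/2, d + window/2); days with no records are NaN.
    """
    sub = df[df["class_label"] == class_label]
    t = sub["day_postpartum"].to_numpy(dtype=float)
    mm = sub["mm_percent"].to_numpy(dtype=float)
    half = window_days / 2.0
    out = {}
    for d in days:
        sel = mm[(t >= d - half) & (t < d + half)]
        out[d] = float(np.median(sel)) if sel.size else np.nan
    return pd.Series(out, name=f"moving_median_{class_label}")
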