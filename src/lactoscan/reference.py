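"""Day-postpartum normative MM% percentile reference charts.

The chart is built from scans of the "normal" breastfeeding class: for each
day-postpartum bin, the 15th / 50th / 85th empirical percentiles of MM% are
computed from the records falling in the bin's smoothing window.  Bins are
daily for the first 21 days postpartum and coarser (roughly weekly, then
open-ended) afterwards.  Smoothing follows the scheme used when the chart
concept was introduced: a +-24 h window around each of the first three daily
bins, and a trailing -24 h extension for all later bins.

Individual scans are then screened against the chart: a scan strictly below
the day-matched 15th-percentile line is flagged as delayed maturation.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyChartError, ValidationError

DEFAULT_LEVELS = (15, 50, 85)

#: Daily bins whose start is <= this value get the symmetric +-24 h window.
EARLY_WINDOW_LAST_START = 2


@dataclass(frozen=True)
class DayBin:
    """Half-open day-postpartum interval [start, end); end may be +inf."""

    start: float
    end: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValidationError(f"bin start {self.start} must be < end {self.end}")

    def contains(self, day: float) -> bool:
        return self.start <= day < self.end

    def label(self) -> str:
        end = "inf" if math.isinf(self.end) else f"{self.end:g}"
        return f"[{self.start:g},{end})"


def default_bins() -> list[DayBin]:
    """Standard binning: 21 daily bins, then [21,28), [28,35), [35,45), [45,60), [60,inf)."""
    bins = [DayBin(float(d), float(d + 1)) for d in range(21)]
    for lo, hi in [(21, 28), (28, 35), (35, 45), (45, 60)]:
        bins.append(DayBin(float(lo), float(hi)))
    bins.append(DayBin(60.0, math.inf))
    return bins


def bins_from_edges(edges: Sequence[float], open_ended: bool = True) -> list[DayBin]:
    bins = [DayBin(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]
    if open_ended:
        bins.append(DayBin(float(edges[-1]), math.inf))
    return bins


@dataclass(frozen=True)
class ReferenceChart:
    """Percentile chart: ``values[i, j]`` is the j-th level for bin i (NaN = missing)."""

    bins: tuple
    levels: tuple
    values: np.ndarray
    n_per_bin: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.shape != (len(self.bins), len(self.levels)):
            raise ValidationError("values matrix shape does not match bins x levels")
        diffs = np.diff(self.values, axis=1)
        if np.any(diffs[~np.isnan(diffs)] < 0):
            raise ValidationError("percentile ordering violated within a bin")

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "bin_start_day": [b.start for b in self.bins],
            "bin_end_day": [b.end for b in self.bins],
            "n": self.n_per_bin,
        }
        for j, lev in enumerate(self.levels):
            rows[f"p{lev}"] = self.values[:, j]
        return pd.DataFrame(rows)


def _as_day_mm(records) -> tuple[np.ndarray, np.ndarray]:
    """Accept a list of ScanRecord or a DataFrame with day_postpartum/mm_percent."""
    if isinstance(records, pd.DataFrame):
        return (
            records["day_postpartum"].to_numpy(dtype=float),
            records["mm_percent"].to_numpy(dtype=float),
        )
    days = np.array([r.day_postpartum for r in records], dtype=float)
    mm = np.array([r.mm_percent for r in records], dtype=float)
    return days, mm


def window_bounds(
    bin_: DayBin,
    lower_offset: float = 1.0,
    upper_offset: float = 1.0,
    early_last_start: float = EARLY_WINDOW_LAST_START,
) -> tuple[float, float]:
    """Smoothing window [lo, hi) for a bin.

    Daily bins starting at day <= ``early_last_start`` get the symmetric
    +-24 h window [start - lower, end + upper); later bins only the trailing
    extension [start - lower, end).  The window never reaches below day 0.
    """
    lo = max(bin_.start - lower_offset, 0.0)
    if bin_.start <= early_last_start:
        hi = bin_.end + upper_offset
    else:
        hi = bin_.end
    return lo, hi


def select_window(records, bin_: DayBin, lower_offset: float = 1.0, upper_offset: float = 1.0):
    """Subset of records inside the bin's smoothing window."""
    lo, hi = window_bounds(bin_, lower_offset, upper_offset)
    if isinstance(records, pd.DataFrame):
        days = records["day_postpartum"].to_numpy(dtype=float)
        return records[(days >= lo) & (days < hi)]
    return [r for r in records if lo <= r.day_postpartum < hi]


def build_reference(
    records,
    bins: Sequence[DayBin] | None = None,
    levels: Sequence[int] = DEFAULT_LEVELS,
    *,
    min_n: int = 5,
    lower_offset: float = 1.0,
    upper_offset: float = 1.0,
    provenance: dict | None = None,
) -> ReferenceChart:
    """Build the percentile chart from normal-class scans.

    Per bin, empirical quantiles (linear interpolation between order
    statistics) of the windowed MM% values; bins whose window holds fewer
    than ``min_n`` records are emitted as missing (NaN) with their count.
    """
    if bins is None:
        bins = default_bins()
    days, mm = _as_day_mm(records)
    qs = [lev / 100.0 for lev in levels]
    values = np.full((len(bins), len(levels)), np.nan)
    n_per_bin = np.zeros(len(bins), dtype=int)
    for i, b in enumerate(bins):
        lo, hi = window_bounds(b, lower_offset, upper_offset)
        sel = mm[(days >= lo) & (days < hi)]
        n_per_bin[i] = sel.size
        if sel.size >= max(min_n, 1):
            values[i, :] = np.quantile(sel, qs, method="linear")
    if not np.any(np.isfinite(values)):
        raise EmptyChartError(
            f"no bin reached min_n={min_n} records (total records: {days.size})"
        )
    prov = dict(provenance or {})
    prov.setdefault("n_source_records", int(days.size))
    prov.setdefault("min_n", int(min_n))
    prov.setdefault("smoothing_offsets", [lower_offset, upper_offset])
    return ReferenceChart(
        bins=tuple(bins),
        levels=tuple(int(v) for v in levels),
        values=values,
        n_per_bin=n_per_bin,
        provenance=prov,
    )


def lookup(chart: ReferenceChart, day_postpartum: float, level: int) -> float | None:
    """Chart value for the bin containing ``day_postpartum``; None if missing."""
    if day_postpartum < 0:
        raise ValidationError(f"day_postpartum must be >= 0, got {day_postpartum}")
    try:
        j = chart.levels.index(int(level))
    except ValueError:
        raise ValidationError(f"level {level} not in chart levels {chart.levels}") from None
    for i, b in enumerate(chart.bins):
        if b.contains(day_postpartum):
            val = chart.values[i, j]
            return None if np.isnan(val) else float(val)
    return None


BELOW = "below"
AT_OR_ABOVE = "at_or_above"
NO_REFERENCE = "no_reference"


def flag_scan(record, chart: ReferenceChart, level: int = 15) -> str:
    """Screen one scan against the day-matched percentile line.

    Strictly-below semantics: a scan exactly on the line is ``at_or_above``.
    ``record`` may be a ScanRecord or anything with day_postpartum/mm_percent.
    """
    if isinstance(record, dict):
        day, mm = record["day_postpartum"], record["mm_percent"]
    else:
        day, mm = record.day_postpartum, record.mm_percent
    threshold = lookup(chart, day, level)
    if threshold is None:
        return NO_REFERENCE
    return BELOW if mm < threshold else AT_OR_ABOVE


def flag_frame(df: pd.DataFrame, chart: ReferenceChart, level: int = 15) -> pd.Series:
    """Vector flag for a records DataFrame; returns a Series of flag strings."""
    j = chart.levels.index(int(level))
    days = df["day_postpartum"].to_numpy(dtype=float)
    mm = df["mm_percent"].to_numpy(dtype=float)
    out = np.full(len(df), NO_REFERENCE, dtype=object)
    for i, b in enumerate(chart.bins):
        thr = chart.values[i, j]
        if np.isnan(thr):
            continue
        in_bin = (days >= b.start) & (days < b.end)
        out[in_bin] = np.where(mm[in_bin] < thr, BELOW, AT_OR_ABOVE)
    return pd.Series(out, index=df.index, name="flag")


# ---------------------------------------------------------------------------
# Serialization: CSV table + JSON sidecar with provenance.


def chart_hash(chart: ReferenceChart) -> str:
    payload = {
        "bins": [[b.start, b.end] for b in chart.bins],
        "levels": list(chart.levels),
        "values": [[None if np.isnan(v) else v for v in row] for row in chart.values],
        "n_per_bin": chart.n_per_bin.tolist(),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def save_chart(chart: ReferenceChart, path) -> None:
    path = Path(path)
    chart.to_frame().to_csv(path, index=False)
    sidecar = {
        "levels": list(chart.levels),
        "provenance": chart.provenance,
        "chart_hash": chart_hash(chart),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_chart(path) -> ReferenceChart:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    levels = tuple(int(v) for v in sidecar["levels"])
    bins = tuple(DayBin(s, e) for s, e in zip(df["bin_start_day"], df["bin_end_day"]))
    values = df[[f"p{lev}" for lev in levels]].to_numpy(dtype=float)
    return ReferenceChart(
        bins=bins,
        levels=levels,
        values=values,
        n_per_bin=df["n"].to_numpy(dtype=int),
        provenance=sidecar["provenance"],
    )
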