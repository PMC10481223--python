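"""Scan records and the retrospective three-way breastfeeding classification.

One scan record joins a single MM% observation with the feeding context
reported at the time of the scan: exclusivity category, recent formula use,
the daily formula fraction when known, and free problem tags.  Records are
retrospectively assigned to one of three breastfeeding classes —

``normal``
    exclusive / full / full-own-milk / predominant (>= 80% mother's milk)
    feeding with no problem tags associated with low milk supply;
``low_supply``
    formula feeding (non-exclusive since birth, formula in the 24 h before
    the scan) together with supply-associated problem tags, or
    mother-reported supply indicators with > 20% of daily feeds as formula;
``bf_problems``
    partial feeding with no problem tagging at all, or predominant feeding
    that nevertheless carries supply-associated tags.

Classes reflect reported status only — milk supply is not directly measured
— and overlapping rules are resolved with the precedence
low_supply > bf_problems > normal.  Every classification carries the id of
the rule that fired as an audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from typing import Iterable

import pandas as pd

from .errors import SchemaError, ValidationError


class Reporter(str, Enum):
    provider = "provider"
    mother = "mother"


class FeedingStatus(str, Enum):
    exclusive = "exclusive"
    full_breastfeeding = "full_breastfeeding"
    full_own_milk = "full_own_milk"
    predominant_80plus = "predominant_80plus"
    partial = "partial"
    mostly_formula = "mostly_formula"


class ProblemTag(str, Enum):
    latch_problem = "latch_problem"
    tongue_tie = "tongue_tie"
    low_weight_gain = "low_weight_gain"
    low_milk_supply = "low_milk_supply"
    slow_weight_gain = "slow_weight_gain"
    breast_pain = "breast_pain"
    nipple_pain = "nipple_pain"


class Label(str, Enum):
    normal = "normal"
    low_supply = "low_supply"
    bf_problems = "bf_problems"
    unclassified = "unclassified"


#: Tags operationalising "problems associated with ineffective breastfeeding
#: and/or low milk supply".  Breast/nipple pain are separate conditions and
#: do not trigger the supply rules on their own.
SUPPLY_TAGS = frozenset(
    {
        ProblemTag.latch_problem,
        ProblemTag.tongue_tie,
        ProblemTag.low_weight_gain,
        ProblemTag.slow_weight_gain,
        ProblemTag.low_milk_supply,
    }
)

#: Tag set for the predominant-feeding-with-problems rule (B2).
B2_TAGS = frozenset(
    {
        ProblemTag.latch_problem,
        ProblemTag.tongue_tie,
        ProblemTag.low_weight_gain,
        ProblemTag.low_milk_supply,
    }
)

#: Feeding categories counted as mother's-own-milk feeding for the normal rule.
NORMAL_FEEDING = frozenset(
    {
        FeedingStatus.exclusive,
        FeedingStatus.full_breastfeeding,
        FeedingStatus.full_own_milk,
        FeedingStatus.predominant_80plus,
    }
)

NO_FORMULA_FEEDING = frozenset(
    {FeedingStatus.exclusive, FeedingStatus.full_breastfeeding, FeedingStatus.full_own_milk}
)

PARTIAL_FEEDING = frozenset({FeedingStatus.partial, FeedingStatus.mostly_formula})

SCANS_COLUMNS = [
    "mother_id",
    "baby_birth",
    "scan_time",
    "breast_side",
    "mm_percent",
    "reporter",
    "feeding_status",
    "formula_fraction_daily",
    "formula_last_24h",
    "problem_tags",
]


@dataclass(frozen=True)
class ScanRecord:
    """One MM% observation with its feeding context at scan time."""

    mother_id: str
    baby_birth: datetime
    scan_time: datetime
    breast_side: str
    mm_percent: float
    reporter: Reporter
    feeding_status: FeedingStatus
    formula_last_24h: bool
    problem_tags: frozenset = frozenset()
    formula_fraction_daily: float | None = None

    def __post_init__(self):
        # Coerce string inputs to the enums (they are str-valued enums).
        object.__setattr__(self, "reporter", Reporter(self.reporter))
        object.__setattr__(self, "feeding_status", FeedingStatus(self.feeding_status))
        object.__setattr__(
            self, "problem_tags", frozenset(ProblemTag(t) for t in self.problem_tags)
        )
        if self.scan_time < self.baby_birth:
            raise ValidationError("negative day_postpartum: scan_time before baby_birth")
        if not 0.0 <= self.mm_percent <= 100.0:
            raise ValidationError(f"mm_percent must be in [0, 100], got {self.mm_percent}")
        if self.breast_side not in ("left", "right"):
            raise ValidationError(f"breast_side must be left|right, got {self.breast_side!r}")
        conflicts = []
        if self.feeding_status in NO_FORMULA_FEEDING and self.formula_last_24h:
            conflicts.append(f"{self.feeding_status.value} with formula_last_24h=true")
        if self.formula_fraction_daily is not None:
            if not 0.0 <= self.formula_fraction_daily <= 1.0:
                conflicts.append(
                    f"formula_fraction_daily {self.formula_fraction_daily} outside [0, 1]"
                )
            elif self.feeding_status is FeedingStatus.exclusive and self.formula_fraction_daily > 0:
                conflicts.append("exclusive feeding with formula_fraction_daily > 0")
            elif (
                self.feeding_status is FeedingStatus.predominant_80plus
                and self.formula_fraction_daily > 0.2
            ):
                conflicts.append("predominant_80plus requires formula_fraction_daily <= 0.2")
        if conflicts:
            raise ValidationError("inconsistent record: " + "; ".join(conflicts))

    @property
    def day_postpartum(self) -> float:
        """Continuous days since birth (scan minus birth over 24 h)."""
        return (self.scan_time - self.baby_birth).total_seconds() / 86400.0


@dataclass(frozen=True)
class FeedingClass:
    label: Label
    rule_fired: str

    def __post_init__(self):
        if self.label is not Label.unclassified and not self.rule_fired:
            raise ValidationError("rule_fired must be non-empty for classified records")


def classify_record(record: ScanRecord) -> FeedingClass:
    """Assign the retrospective breastfeeding class for one scan record.

    Deterministic decision list with precedence low_supply > bf_problems >
    normal; the returned ``rule_fired`` identifies which rule matched.
    """
    tags = frozenset(record.problem_tags)
    frac = record.formula_fraction_daily

    # low supply -----------------------------------------------------------
    if (
        record.reporter is Reporter.provider
        and record.feeding_status in PARTIAL_FEEDING
        and record.formula_last_24h
        and tags & SUPPLY_TAGS
    ):
        return FeedingClass(Label.low_supply, "L1:provider-formula-with-supply-tags")
    if (
        record.reporter is Reporter.mother
        and (ProblemTag.low_milk_supply in tags or ProblemTag.slow_weight_gain in tags)
        and frac is not None
        and frac > 0.2
    ):
        return FeedingClass(Label.low_supply, "L2:mother-supply-indicators-significant-formula")

    # breastfeeding problems ----------------------------------------------
    if record.feeding_status in PARTIAL_FEEDING and record.formula_last_24h and not tags:
        return FeedingClass(Label.bf_problems, "B1:partial-no-tags")
    if record.feeding_status is FeedingStatus.predominant_80plus and tags & B2_TAGS:
        return FeedingClass(Label.bf_problems, "B2:predominant-with-supply-tags")

    # normal ---------------------------------------------------------------
    if record.feeding_status in NORMAL_FEEDING and not tags & SUPPLY_TAGS:
        return FeedingClass(Label.normal, "N1:own-milk-no-supply-tags")

    return FeedingClass(Label.unclassified, "")


def classify_records(records: Iterable[ScanRecord]) -> list[FeedingClass]:
    return [classify_record(r) for r in records]


# ---------------------------------------------------------------------------
# CSV interface


def _parse_row(row) -> ScanRecord:
    tags_cell = row.problem_tags
    if pd.isna(tags_cell) or str(tags_cell).strip() == "":
        tags = frozenset()
    else:
        tags = frozenset(ProblemTag(t.strip()) for t in str(tags_cell).split(";") if t.strip())
    frac = row.formula_fraction_daily
    frac = None if pd.isna(frac) else float(frac)
    formula24 = str(row.formula_last_24h).strip().lower() in ("true", "1", "yes")
    return ScanRecord(
        mother_id=str(row.mother_id),
        baby_birth=pd.Timestamp(row.baby_birth).to_pydatetime(),
        scan_time=pd.Timestamp(row.scan_time).to_pydatetime(),
        breast_side=str(row.breast_side),
        mm_percent=float(row.mm_percent),
        reporter=Reporter(str(row.reporter)),
        feeding_status=FeedingStatus(str(row.feeding_status)),
        formula_last_24h=formula24,
        problem_tags=tags,
        formula_fraction_daily=frac,
    )


def records_from_frame(df: pd.DataFrame) -> list[ScanRecord]:
    """Build ScanRecord objects from an in-memory scans table (strict: raises on bad rows)."""
    missing = [c for c in SCANS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"scans table missing columns: {missing}")
    return [_parse_row(row) for row in df.itertuples(index=False)]


def read_scan_records(path) -> tuple[list[ScanRecord], list[dict]]:
    """Read a scan-records CSV.

    Returns ``(records, rejects)``: malformed rows are collected into a
    rejects report (row index + reason), never silently dropped.
    """
    df = pd.read_csv(path)
    missing = [c for c in SCANS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"scan-records CSV missing columns: {missing}")
    records: list[ScanRecord] = []
    rejects: list[dict] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(_parse_row(row))
        except (ValidationError, ValueError, KeyError) as exc:
            reason = str(exc)
            if "negative day_postpartum" in reason:
                reason = "negative day_postpartum"
            rejects.append({"row": i, "reason": reason})
    return records, rejects


def records_to_frame(
    records: Iterable[ScanRecord], classes: Iterable[FeedingClass] | None = None
) -> pd.DataFrame:
    """Tabulate records (optionally with their classification) for analysis."""
    rows = []
    for rec in records:
        rows.append(
            {
                "mother_id": rec.mother_id,
                "baby_birth": rec.baby_birth,
                "scan_time": rec.scan_time,
                "breast_side": rec.breast_side,
                "day_postpartum": rec.day_postpartum,
                "mm_percent": rec.mm_percent,
                "reporter": rec.reporter.value,
                "feeding_status": rec.feeding_status.value,
                "formula_fraction_daily": rec.formula_fraction_daily,
                "formula_last_24h": rec.formula_last_24h,
                "problem_tags": ";".join(sorted(t.value for t in rec.problem_tags)),
            }
        )
    df = pd.DataFrame(rows)
    if classes is not None:
        classes = list(classes)
        df["class_label"] = [c.label.value for c in classes]
        df["rule_fired"] = [c.rule_fired for c in classes]
    return df


def classification_summary(
    records: list[ScanRecord], classes: list[FeedingClass] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class counts and per-tag frequencies.

    Tag percentages are computed per class over the records carrying at
    least one tag; a record with k tags contributes to k tag rows, so
    percentages within a class may sum to more than 100.
    """
    if classes is None:
        classes = classify_records(records)
    if not records:
        return (
            pd.DataFrame(columns=["class_label", "n"]),
            pd.DataFrame(columns=["class_label", "tag", "n", "percent_of_tagged"]),
        )
    counts: dict[str, int] = {}
    tagged: dict[str, int] = {}
    tag_counts: dict[tuple[str, str], int] = {}
    for rec, cls in zip(records, classes):
        lab = cls.label.value
        counts[lab] = counts.get(lab, 0) + 1
        if rec.problem_tags:
            tagged[lab] = tagged.get(lab, 0) + 1
            for tag in rec.problem_tags:
                key = (lab, tag.value)
                tag_counts[key] = tag_counts.get(key, 0) + 1
    count_df = pd.DataFrame(
        sorted(counts.items()), columns=["class_label", "n"]
    )
    tag_rows = [
        {
            "class_label": lab,
            "tag": tag,
            "n": n,
            "percent_of_tagged": 100.0 * n / tagged[lab],
        }
        for (lab, tag), n in sorted(tag_counts.items())
    ]
    tag_df = pd.DataFrame(tag_rows, columns=["class_label", "tag", "n", "percent_of_tagged"])
    return count_df, tag_df
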