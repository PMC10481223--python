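from datetime import datetime, timedelta

import pandas as pd
import pytest

from lactoscan import classify_records, records_from_frame, records_to_frame
from lactoscan.cohort import CohortConfig, SimulatedCohort, simulate_scans

BIRTH = datetime(2024, 1, 1)


def make_record_kwargs(**overrides):
    """Baseline valid ScanRecord kwargs; override fields per test."""
    base = dict(
        mother_id="m0",
        baby_birth=BIRTH,
        scan_time=BIRTH + timedelta(days=3),
        breast_side="left",
        mm_percent=80.0,
        reporter="provider",
        feeding_status="exclusive",
        formula_last_24h=False,
        problem_tags=frozenset(),
        formula_fraction_daily=None,
    )
    base.update(overrides)
    return base


def classified_frame(sim: SimulatedCohort) -> pd.DataFrame:
    """Simulator scans -> records DataFrame with class labels and day_postpartum."""
    recs = records_from_frame(sim.scans)
    return records_to_frame(recs, classify_records(recs))


@pytest.fixture(scope="session")
def default_cohort() -> SimulatedCohort:
    return simulate_scans(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def default_frame(default_cohort) -> pd.DataFrame:
    return classified_frame(default_cohort)
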