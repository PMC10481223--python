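"""Normative percentile chart: bins, smoothing windows, quantiles, lookup, flagging."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lactoscan import (
    AT_OR_ABOVE,
    BELOW,
    NO_REFERENCE,
    DayBin,
    build_reference,
    default_bins,
    flag_scan,
    load_chart,
    lookup,
    save_chart,
    select_window,
)
from lactoscan.errors import EmptyChartError, ValidationError
from lactoscan.reference import chart_hash, flag_frame, window_bounds


def frame(days, mm):
    return pd.DataFrame({"day_postpartum": days, "mm_percent": mm})


class TestDefaultBins:
    def test_26_bins_daily_then_coarse(self):
        bins = default_bins()
        assert len(bins) == 26
        assert (bins[0].start, bins[0].end) == (0.0, 1.0)
        assert all(b.end - b.start == 1.0 for b in bins[:21])
        assert [(b.start, b.end) for b in bins[21:25]] == [
            (21.0, 28.0),
            (28.0, 35.0),
            (35.0, 45.0),
            (45.0, 60.0),
        ]
        assert math.isinf(bins[-1].end)

    def test_bins_ordered_and_non_overlapping(self):
        bins = default_bins()
        assert all(a.end == b.start for a, b in zip(bins, bins[1:]))


class TestSelectWindow:
    def test_early_bins_get_symmetric_24h_window(self):
        # bin [1,2): window [0,3) -> day 2.5 included
        assert window_bounds(DayBin(1, 2)) == (0.0, 3.0)
        sel = select_window(frame([2.5], [50.0]), DayBin(1, 2))
        assert len(sel) == 1

    def test_later_bins_get_trailing_extension_only(self):
        # bin [5,6): window [4,6) -> 6.1 out, 4.2 in
        assert window_bounds(DayBin(5, 6)) == (4.0, 6.0)
        sel = select_window(frame([6.1, 4.2], [50.0, 60.0]), DayBin(5, 6))
        assert sel["day_postpartum"].tolist() == [4.2]

    def test_window_floored_at_day_zero(self):
        assert window_bounds(DayBin(0, 1)) == (0.0, 2.0)

    def test_offsets_zero_disable_smoothing(self):
        assert window_bounds(DayBin(1, 2), 0.0, 0.0) == (1.0, 2.0)


class TestBuildReference:
    def test_constant_sample_gives_constant_percentiles(self):
        df = frame([0.5] * 6, [70.0] * 6)
        chart = build_reference(df, bins=[DayBin(0, 1)])
        assert chart.values[0].tolist() == [70.0, 70.0, 70.0]

    def test_quantiles_match_naive_oracle_on_ten_points(self):
        vals = [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
        df = frame([0.5] * 10, vals)
        chart = build_reference(df, bins=[DayBin(0, 1)])
        expected = np.quantile(np.array(vals, float), [0.15, 0.50, 0.85])
        assert chart.values[0] == pytest.approx(expected)

    def test_early_windows_share_records_across_adjacent_bins(self):
        # day-0.5 records fall in the +-24 h windows of both bin [0,1) and [1,2)
        df = frame([0.5] * 3, [50.0] * 3)
        chart = build_reference(df, bins=[DayBin(0, 1), DayBin(1, 2)], min_n=3)
        assert chart.n_per_bin.tolist() == [3, 3]
        assert np.isfinite(chart.values).all()

    def test_min_n_threshold_contract(self):
        df = frame([0.5] * 3 + [10.5] * 7, [50.0] * 3 + [80.0] * 7)
        chart = build_reference(df, bins=[DayBin(0, 1), DayBin(10, 11)], min_n=5)
        assert np.isnan(chart.values[0]).all() and chart.n_per_bin[0] == 3
        assert np.isfinite(chart.values[1]).all() and chart.n_per_bin[1] == 7

    def test_no_usable_bins_raises(self):
        with pytest.raises(EmptyChartError):
            build_reference(frame([0.5], [50.0]), bins=[DayBin(0, 1)], min_n=5)

    def test_oracle_equivalence_with_smoothing_disabled(self):
        """With zero offsets, bit-equal to a per-bin sort-and-interpolate oracle."""
        rng = np.random.default_rng(123)
        days = rng.uniform(0, 70, 1000)
        mm = rng.uniform(0, 100, 1000)
        df = frame(days, mm)
        bins = default_bins()
        chart = build_reference(df, bins=bins, min_n=1, lower_offset=0.0, upper_offset=0.0)
        for i, b in enumerate(bins):
            sel = np.sort(mm[(days >= b.start) & (days < b.end)])
            expected = np.quantile(sel, [0.15, 0.50, 0.85], method="linear")
            assert chart.values[i].tolist() == expected.tolist()  # bit-equal

    @settings(deadline=None, max_examples=40)
    @given(st.data())
    def test_percentile_ordering_holds_for_arbitrary_inputs(self, data):
        n = data.draw(st.integers(5, 60))
        days = data.draw(
            st.lists(st.floats(0, 80), min_size=n, max_size=n)
        )
        mm = data.draw(
            st.lists(st.floats(0, 100), min_size=n, max_size=n)
        )
        try:
            chart = build_reference(frame(days, mm), min_n=1)
        except EmptyChartError:
            return
        finite = chart.values[np.isfinite(chart.values).all(axis=1)]
        assert np.all(np.diff(finite, axis=1) >= 0)


class TestLookupAndFlag:
    def chart(self):
        rng = np.random.default_rng(0)
        days = np.concatenate([rng.uniform(0, 60, 400), rng.uniform(60, 90, 20)])
        mm = np.clip(100 * (1 - np.exp(-days / 3)) + rng.normal(0, 5, 420), 0, 100)
        return build_reference(frame(days, mm))

    def test_lookup_day_in_bin(self):
        chart = self.chart()
        assert lookup(chart, 0.5, 50) == pytest.approx(chart.values[0, 1])

    def test_lookup_far_day_hits_open_ended_bin(self):
        chart = self.chart()
        assert lookup(chart, 400.0, 50) == pytest.approx(chart.values[-1, 1])

    def test_day_21_falls_in_coarse_bin_half_open(self):
        chart = self.chart()
        assert lookup(chart, 21.0, 50) == pytest.approx(chart.values[21, 1])

    def test_negative_day_rejected(self):
        with pytest.raises(ValidationError):
            lookup(self.chart(), -1.0, 50)

    def test_flag_below_and_strict_equality(self):
        chart = build_reference(frame([5.5] * 6, [50, 55, 60, 65, 70, 75]), bins=[DayBin(5, 6)])
        threshold = chart.values[0, 0]
        rec = {"day_postpartum": 5.5, "mm_percent": threshold - 1.0}
        assert flag_scan(rec, chart) == BELOW
        rec_eq = {"day_postpartum": 5.5, "mm_percent": threshold}
        assert flag_scan(rec_eq, chart) == AT_OR_ABOVE

    def test_missing_bin_flags_no_reference(self):
        chart = build_reference(frame([5.5] * 6, [50.0] * 6), bins=[DayBin(5, 6), DayBin(30, 31)])
        assert flag_scan({"day_postpartum": 30.5, "mm_percent": 50.0}, chart) == NO_REFERENCE

    def test_flag_frame_matches_scalar_flagging(self):
        chart = self.chart()
        rng = np.random.default_rng(5)
        df = frame(rng.uniform(0, 80, 200), rng.uniform(0, 100, 200))
        vec = flag_frame(df, chart)
        scalars = [
            flag_scan({"day_postpartum": d, "mm_percent": m}, chart)
            for d, m in zip(df["day_postpartum"], df["mm_percent"])
        ]
        assert vec.tolist() == scalars


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(9)
        days = rng.uniform(0, 70, 600)
        mm = np.clip(100 * (1 - np.exp(-days / 2)) + rng.normal(0, 6, 600), 0, 100)
        chart = build_reference(frame(days, mm), provenance={"config_hash": "abc123"})
        path = tmp_path / "chart.csv"
        save_chart(chart, path)
        loaded = load_chart(path)
        assert chart_hash(loaded) == chart_hash(chart)
        np.testing.assert_array_equal(loaded.values, chart.values)
        assert loaded.provenance["config_hash"] == "abc123"
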