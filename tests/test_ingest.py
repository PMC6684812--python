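"""Record parsing, screening, anthrome labeling, aggregation and summaries."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import firecycles as fc
from firecycles.ingest import (
    read_anthrome_grid,
    read_count_series_csv,
    write_anthrome_grid,
    write_count_series_csv,
    write_mcd14ml,
)

MONDAY = dt.date(2002, 7, 8)


def _make_records(**overrides):
    base = dict(
        acq_date=pd.to_datetime([MONDAY] * 4),
        acq_time=np.array([630, 630, 810, 810]),
        satellite=pd.array(["T", "T", "A", "A"], dtype="string"),
        lat=np.array([10.0, 10.5, -5.0, 0.0]),
        lon=np.array([20.0, 21.0, 22.0, 23.0]),
        confidence=np.array([100, 10, 30, 90]),
        type_code=np.array([0, 1, 2, 3]),
    )
    base.update(overrides)
    return fc.FireRecordSet.from_columns(**base)


class TestReadWrite:
    def test_three_line_file_roundtrip(self, tmp_path):
        p = tmp_path / "fires.txt"
        p.write_text(
            "20020708,1030,T,10.12345,20.54321,310.0,290.0,0,12.3,85,0\n"
            "20020709,1330,A,-5.00000,100.00000,305.0,288.0,1,5.0,40,0\n"
            "20020710,0230,Aqua,60.00000,-120.00000,300.0,285.0,0,2.0,100,1\n"
        )
        recs = fc.read_mcd14ml(p)
        assert len(recs) == 3 and recs.n_dropped == 0 and recs.n_malformed == 0
        df = recs.records
        assert df.loc[0, "lat"] == pytest.approx(10.12345)
        assert df.loc[0, "acq_time"] == 10 * 60 + 30
        assert df.loc[2, "satellite"] == "A"
        assert list(df["type_code"]) == [0, 0, 1]

    def test_out_of_range_latitude_dropped(self, tmp_path):
        p = tmp_path / "fires.txt"
        p.write_text(
            "20020708,1030,T,99.0,20.0,310.0,290.0,0,12.3,85,0\n"
            "20020708,1030,T,10.0,20.0,310.0,290.0,0,12.3,85,0\n"
        )
        recs = fc.read_mcd14ml(p)
        assert len(recs) == 1 and recs.n_dropped == 1

    def test_malformed_line_counted(self, tmp_path):
        p = tmp_path / "fires.txt"
        p.write_text("not,a,record\n20020708,1030,T,10.0,20.0,310,290,0,1,85,0\n")
        recs = fc.read_mcd14ml(p)
        assert len(recs) == 1 and recs.n_malformed == 1

    def test_header_missing_required_column_fails(self, tmp_path):
        p = tmp_path / "fires.txt"
        p.write_text("YYYYMMDD,HHMM,sat,lat,lon,conf\n20020708,1030,T,10.0,20.0,85\n")
        with pytest.raises(ValueError, match="type"):
            fc.read_mcd14ml(p)

    def test_written_records_roundtrip(self, tmp_path, small_record_set):
        recs, _ = small_record_set
        p = tmp_path / "out.txt"
        write_mcd14ml(recs, p)
        back = fc.read_mcd14ml(p)
        assert len(back) == len(recs)
        np.testing.assert_allclose(
            back.records["lat"].to_numpy(), recs.records["lat"].to_numpy(), atol=1e-5
        )


class TestScreening:
    def test_default_keeps_vegetation_fires_only(self):
        recs = _make_records()
        kept = fc.screen_records(recs)
        assert len(kept) == 1 and kept.records.loc[0, "type_code"] == 0

    def test_confidence_threshold(self):
        recs = _make_records(type_code=np.zeros(4, dtype=int), confidence=np.array([10, 30, 90, 5]))
        assert len(fc.screen_records(recs, min_confidence=30)) == 2

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(0)
        n = 100
        recs = _make_records(
            acq_date=pd.to_datetime([MONDAY] * n),
            acq_time=np.full(n, 630),
            satellite=pd.array(["T"] * n, dtype="string"),
            lat=rng.uniform(-60, 60, n),
            lon=rng.uniform(-170, 170, n),
            confidence=rng.integers(0, 101, n),
            type_code=rng.integers(0, 4, n),
        )
        kept = fc.screen_records(recs, min_confidence=40, keep_types={0, 2})
        brute = [
            i
            for i in range(n)
            if recs.records.loc[i, "type_code"] in (0, 2) and recs.records.loc[i, "confidence"] >= 40
        ]
        assert list(kept.records.index) == list(range(len(brute)))
        assert len(kept) == len(brute)


class TestAnthromeGrid:
    def test_ascii_roundtrip(self, tmp_path, toy_grid):
        p = tmp_path / "grid.asc"
        write_anthrome_grid(toy_grid, p)
        back = read_anthrome_grid(p)
        np.testing.assert_array_equal(back.codes, toy_grid.codes)
        assert back.cellsize == toy_grid.cellsize

    def test_small_grid_layout(self, tmp_path):
        p = tmp_path / "grid.asc"
        p.write_text(
            "ncols 2\nnrows 2\nxllcorner 0.0\nyllcorner 0.0\ncellsize 0.5\n"
            "NODATA_value -9999\n31 41\n51 61\n"
        )
        grid = read_anthrome_grid(p)
        np.testing.assert_array_equal(grid.codes, [[31, 41], [51, 61]])

    def test_short_data_row_fails_with_row_number(self, tmp_path):
        p = tmp_path / "grid.asc"
        p.write_text(
            "ncols 2\nnrows 2\nxllcorner 0.0\nyllcorner 0.0\ncellsize 0.5\n"
            "NODATA_value -9999\n31 41\n51\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_anthrome_grid(p)


class TestAssignAnthromes:
    def test_cell_center_and_nodata(self):
        grid = fc.make_toy_anthrome_grid(
            2, 2, {(0, 2, 0, 1): 31, (0, 2, 1, 2): -9999}, cellsize=1.0
        )
        recs = _make_records(
            acq_date=pd.to_datetime([MONDAY] * 2),
            acq_time=np.array([630, 630]),
            satellite=pd.array(["T", "A"], dtype="string"),
            lat=np.array([1.5, 1.5]),
            lon=np.array([0.5, 1.5]),
            confidence=np.array([100, 100]),
            type_code=np.array([0, 0]),
        )
        labeled = fc.assign_anthromes(recs, grid)
        assert labeled.records.loc[0, "anthrome_code"] == 31
        assert pd.isna(labeled.records.loc[1, "anthrome_code"])
        assert len(labeled) == 2  # nodata record retained

    def test_missing_code_in_mapping_fails(self, toy_grid):
        recs = _make_records()
        with pytest.raises(ValueError, match="51"):
            fc.assign_anthromes(recs, toy_grid, code_to_group={31: "Croplands", 41: "Rangelands"})

    def test_matches_exhaustive_rectangle_scan(self, toy_grid):
        rng = np.random.default_rng(42)
        n = 1000
        lat = rng.uniform(-0.5, 1.5, n)  # includes points outside the grid
        lon = rng.uniform(-0.5, 2.0, n)
        recs = _make_records(
            acq_date=pd.to_datetime([MONDAY] * n),
            acq_time=np.full(n, 630),
            satellite=pd.array(["T"] * n, dtype="string"),
            lat=lat,
            lon=lon,
            confidence=np.full(n, 100),
            type_code=np.zeros(n, dtype=int),
        )
        labeled = fc.assign_anthromes(recs, toy_grid)

        # brute force: test every point against every cell rectangle [S, N) x [W, E)
        expected = []
        for y, x in zip(lat, lon):
            code = None
            for r in range(toy_grid.nrows):
                for c in range(toy_grid.ncols):
                    north = toy_grid.ytopcorner - r * toy_grid.cellsize
                    south = north - toy_grid.cellsize
                    west = toy_grid.xllcorner + c * toy_grid.cellsize
                    east = west + toy_grid.cellsize
                    if south < y <= north and west <= x < east:
                        code = int(toy_grid.codes[r, c])
            expected.append(code)
        got = [
            None if pd.isna(v) else int(v) for v in labeled.records["anthrome_code"]
        ]
        assert got == expected


class TestAggregation:
    def test_single_day_window(self):
        recs = _make_records(type_code=np.zeros(4, dtype=int))
        out = fc.aggregate_daily(recs, MONDAY, MONDAY)
        assert list(out["global"].counts) == [4]

    def test_empty_days_are_zero(self):
        recs = _make_records(type_code=np.zeros(4, dtype=int))
        out = fc.aggregate_daily(recs, MONDAY, MONDAY + dt.timedelta(days=2))
        assert list(out["global"].counts) == [4, 0, 0]

    def test_group_conservation(self, small_record_set, toy_grid):
        recs, _ = small_record_set
        labeled = fc.assign_anthromes(recs, toy_grid)
        start, end = MONDAY, MONDAY + dt.timedelta(days=20)
        per_group = fc.aggregate_daily(labeled, start, end, group_by="anthrome_group")
        total = fc.aggregate_daily(labeled, start, end)["global"]
        stacked = sum(s.counts for s in per_group.values())
        np.testing.assert_array_equal(stacked, total.counts)


class TestCalendar:
    def test_study_period_has_525_full_weeks(self):
        assert fc.count_full_weeks(dt.date(2002, 7, 8), dt.date(2012, 7, 29)) == 525

    def test_single_and_partial_weeks(self):
        assert fc.count_full_weeks(dt.date(2002, 7, 8), dt.date(2002, 7, 14)) == 1
        assert fc.count_full_weeks(dt.date(2002, 7, 8), dt.date(2002, 7, 13)) == 0

    @given(k=st.integers(min_value=1, max_value=10))
    @settings(deadline=None)
    def test_monday_start_counts_k_weeks(self, k):
        assert fc.count_full_weeks(MONDAY, MONDAY + dt.timedelta(days=7 * k - 1)) == k

    def test_trim_from_wednesday(self):
        series = fc.DailyCountSeries(
            start_date=dt.date(2002, 7, 10), counts=np.arange(1, 13), label="x"
        )
        trimmed = fc.trim_to_full_weeks(series)
        assert trimmed.start_date.weekday() == 0
        assert len(trimmed) == 7
        assert trimmed.start_date == dt.date(2002, 7, 15)

    def test_trim_is_identity_on_aligned_series(self):
        series = fc.DailyCountSeries(start_date=MONDAY, counts=np.ones(14, dtype=int))
        trimmed = fc.trim_to_full_weeks(series)
        assert trimmed.start_date == MONDAY and len(trimmed) == 14

    @given(
        start_offset=st.integers(min_value=0, max_value=6),
        n=st.integers(min_value=14, max_value=60),
    )
    @settings(deadline=None)
    def test_trim_always_monday_multiple_of_seven(self, start_offset, n):
        series = fc.DailyCountSeries(
            start_date=MONDAY + dt.timedelta(days=start_offset), counts=np.ones(n, dtype=int)
        )
        trimmed = fc.trim_to_full_weeks(series)
        assert trimmed.start_date.weekday() == 0
        assert len(trimmed) % 7 == 0


class TestWeekdaySummary:
    def test_constant_series(self):
        series = fc.DailyCountSeries(start_date=MONDAY, counts=np.full(14, 10))
        s = fc.weekday_summary(series)
        assert (s["mean"] == 10).all() and (s["sd"] == 0).all()

    def test_sunday_deficit(self):
        counts = np.tile([10, 10, 10, 10, 10, 10, 5], 2)
        series = fc.DailyCountSeries(start_date=MONDAY, counts=counts)
        s = fc.weekday_summary(series)
        assert s.loc[6, "mean"] == 5 and s.loc[6, "sd"] == 0
        assert (s.loc[:5, "mean"] == 10).all()


class TestGridSummary:
    def test_min_weekday_picks_sunday(self):
        dates = [MONDAY + dt.timedelta(days=1)] * 5 + [MONDAY + dt.timedelta(days=6)]
        n = len(dates)
        recs = _make_records(
            acq_date=pd.to_datetime(dates),
            acq_time=np.full(n, 630),
            satellite=pd.array(["T"] * n, dtype="string"),
            lat=np.full(n, 10.2),
            lon=np.full(n, 20.2),
            confidence=np.full(n, 100),
            type_code=np.zeros(n, dtype=int),
        )
        out = fc.grid_summary(recs, statistic="min_weekday")
        assert len(out) == 1 and out.loc[0, "value"] == 7

    def test_count_statistic(self):
        n = 10
        recs = _make_records(
            acq_date=pd.to_datetime([MONDAY] * n),
            acq_time=np.full(n, 630),
            satellite=pd.array(["T"] * n, dtype="string"),
            lat=np.full(n, 0.1),
            lon=np.full(n, 0.1),
            confidence=np.full(n, 100),
            type_code=np.zeros(n, dtype=int),
        )
        out = fc.grid_summary(recs, statistic="count")
        assert len(out) == 1 and out.loc[0, "value"] == 10

    def test_count_matches_brute_force_tally(self):
        rng = np.random.default_rng(3)
        n = 500
        lat = rng.uniform(-10, 10, n)
        lon = rng.uniform(-10, 10, n)
        recs = _make_records(
            acq_date=pd.to_datetime([MONDAY] * n),
            acq_time=np.full(n, 630),
            satellite=pd.array(["T"] * n, dtype="string"),
            lat=lat,
            lon=lon,
            confidence=np.full(n, 100),
            type_code=np.zeros(n, dtype=int),
        )
        out = fc.grid_summary(recs, cellsize=0.5, statistic="count")
        brute: dict[tuple[int, int], int] = {}
        for y, x in zip(lat, lon):
            key = (int(np.floor((90 - y) / 0.5)), int(np.floor((x + 180) / 0.5)))
            brute[key] = brute.get(key, 0) + 1
        got = {(r, c): v for r, c, v in out[["row", "col", "value"]].itertuples(index=False)}
        assert got == brute


class TestSeriesCsv:
    def test_roundtrip(self, tmp_path):
        series = fc.DailyCountSeries(start_date=MONDAY, counts=np.arange(1, 15), label="x")
        p = tmp_path / "counts.csv"
        write_count_series_csv(series, p)
        back = read_count_series_csv(p)
        np.testing.assert_array_equal(back.counts, series.counts)
        assert back.start_date == MONDAY
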