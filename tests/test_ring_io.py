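"""File-format round trips and calendar integrity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringclim import (
    DailyClimate,
    RingDataset,
    RingSeries,
    TreeRecord,
    read_daily_climate,
    read_rwl,
    read_series_csv,
    write_rwl,
    write_series_csv,
)
from ringclim.ring_io import RwlParseError


def _dataset(values_by_id, first_years):
    series = [
        RingSeries(sid, first_years[sid], vals, "TRW") for sid, vals in values_by_id.items()
    ]
    return RingDataset(series=series, proxy_kind="TRW")


class TestRwl:
    def test_round_trip_preserves_dataset(self, tmp_path):
        ds = _dataset(
            {"T001": np.array([1.234, 2.345, 0.567, 3.0]), "T002": np.array([0.5, 0.75])},
            {"T001": 1978, "T002": 1999},
        )
        path = tmp_path / "out.rwl"
        write_rwl(ds, path)
        back = read_rwl(path)
        assert [s.series_id for s in back.series] == ["T001", "T002"]
        for orig, rt in zip(ds.series, back.series):
            assert rt.first_year == orig.first_year
            np.testing.assert_allclose(rt.values, orig.values, atol=5e-4)

    @settings(max_examples=25, deadline=None)
    @given(
        first_year=st.integers(1500, 2015),
        n=st.integers(1, 140),
        precision=st.sampled_from([0.001, 0.01]),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_round_trip_random_to_dialect_precision(self, tmp_path_factory, first_year, n, precision, seed):
        rng = np.random.default_rng(seed)
        vals = np.round(rng.uniform(0, 9, n) / precision) * precision
        ds = _dataset({"RND1": vals}, {"RND1": first_year})
        path = tmp_path_factory.mktemp("rwl") / "r.rwl"
        write_rwl(ds, path, precision=precision)
        back = read_rwl(path)
        assert back.series[0].first_year == first_year
        np.testing.assert_allclose(back.series[0].values, vals, atol=precision / 2)

    def test_sentinel_selects_units(self, tmp_path):
        # -9999 terminated rows are 0.001 mm; 999 terminated rows are 0.01 mm
        p1 = tmp_path / "a.rwl"
        p1.write_text("AAA     1990  1234   500 -9999\n")
        s1 = read_rwl(p1).series[0]
        np.testing.assert_allclose(s1.values, [1.234, 0.5])
        p2 = tmp_path / "b.rwl"
        p2.write_text("BBB     1990   123    50   999\n")
        s2 = read_rwl(p2).series[0]
        np.testing.assert_allclose(s2.values, [1.23, 0.5])

    def test_malformed_line_reports_position(self, tmp_path):
        p = tmp_path / "bad.rwl"
        p.write_text("AAA     1990   abc -9999\n")
        with pytest.raises(RwlParseError, match="bad.rwl:1"):
            read_rwl(p)

    def test_non_contiguous_decades_rejected(self, tmp_path):
        p = tmp_path / "gap.rwl"
        p.write_text("AAA     1990   100   100\nAAA     2005   100 -9999\n")
        with pytest.raises(RwlParseError, match="does not follow"):
            read_rwl(p)

    def test_write_rejects_long_id_bi_and_empty(self, tmp_path):
        long_id = _dataset({"VERYLONGID": np.array([1.0])}, {"VERYLONGID": 2000})
        with pytest.raises(ValueError, match="8 characters"):
            write_rwl(long_id, tmp_path / "x.rwl")
        bi = RingDataset(
            series=[RingSeries("B1", 2000, np.array([2.2, 2.3]), "BI")], proxy_kind="BI"
        )
        with pytest.raises(ValueError, match="CSV"):
            write_rwl(bi, tmp_path / "y.rwl")
        with pytest.raises(ValueError, match="empty"):
            write_rwl(RingDataset(series=[], proxy_kind="TRW"), tmp_path / "z.rwl")

    def test_decadal_layout_single_series(self, tmp_path):
        ds = _dataset({"S1": np.arange(1, 43) * 0.1}, {"S1": 1978})
        path = tmp_path / "s.rwl"
        write_rwl(ds, path)
        lines = path.read_text().strip().splitlines()
        # 1978-1979 | 1980-1989 | ... | 2010-2019 (+ sentinel)
        assert len(lines) == 6
        assert lines[0].split()[1] == "1978" and len(lines[0].split()) == 4
        assert lines[-1].split()[-1] == "-9999"


class TestCalendar:
    def test_series_year_arithmetic(self):
        s = RingSeries("X", 1950, np.ones(71), "TRW")
        assert s.last_year - s.first_year + 1 == len(s.values) == 71

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RingDataset(
                series=[
                    RingSeries("A", 2000, np.ones(3), "TRW"),
                    RingSeries("A", 1990, np.ones(3), "TRW"),
                ],
                proxy_kind="TRW",
            )


class TestSeriesCsv:
    def test_round_trip(self, tmp_path):
        ds = RingDataset(
            series=[RingSeries("B1", 1980, np.array([2.21, 2.35, 2.10]), "BI")],
            proxy_kind="BI",
        )
        path = tmp_path / "bi.csv"
        write_series_csv(ds, path)
        back = read_series_csv(path, "BI")
        assert back == ds

    def test_year_gap_rejected(self, tmp_path):
        p = tmp_path / "gap.csv"
        pd.DataFrame(
            {"series_id": ["A", "A"], "year": [2000, 2002], "value": [1.0, 1.0]}
        ).to_csv(p, index=False)
        with pytest.raises(ValueError, match="consecutive"):
            read_series_csv(p, "TRW")


class TestDailyClimate:
    def test_full_record_length_counts_leap_days(self, tmp_path):
        dates = pd.date_range("1978-01-01", "2019-12-31", freq="D")
        # independent calendar oracle: 42*365 plus one day per leap year
        leap = sum(1 for y in range(1978, 2020) if (y % 4 == 0 and y % 100 != 0) or y % 400 == 0)
        expected = 42 * 365 + leap
        assert expected == 15340
        p = tmp_path / "clim.csv"
        pd.DataFrame({"date": dates.strftime("%Y-%m-%d"), "tmean": 5.0}).to_csv(p, index=False)
        clim = read_daily_climate(p)
        assert len(clim) == 15340
        assert len(clim.gaps) == 0
        assert clim.full_years() == (1978, 2019)

    def test_single_missing_day_listed_as_gap(self, tmp_path):
        dates = pd.date_range("2000-01-01", "2000-12-31", freq="D")
        keep = dates[dates != pd.Timestamp("2000-06-15")]
        p = tmp_path / "gap.csv"
        pd.DataFrame({"date": keep.strftime("%Y-%m-%d"), "tmean": 1.0}).to_csv(p, index=False)
        clim = read_daily_climate(p)
        assert list(clim.gaps) == [pd.Timestamp("2000-06-15")]

    def test_textual_temperature_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("date,tmean\n2000-01-01,1.5\n2000-01-02,oops\n")
        with pytest.raises(ValueError, match="row 3"):
            read_daily_climate(p)

    def test_non_monotone_dates_rejected(self, tmp_path):
        p = tmp_path / "mono.csv"
        p.write_text("date,tmean\n2000-01-02,1.0\n2000-01-01,2.0\n")
        with pytest.raises(ValueError, match="increasing"):
            read_daily_climate(p)

    def test_constructor_validates_alignment(self):
        with pytest.raises(ValueError, match="equal length"):
            DailyClimate("x", pd.DatetimeIndex(["2000-01-01"]), np.array([1.0, 2.0]))


def test_tree_record_validation():
    with pytest.raises(ValueError, match="dbh_final"):
        TreeRecord("T", 0.0, "low")
    with pytest.raises(ValueError, match="elevation_class"):
        TreeRecord("T", 100.0, "mid")
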