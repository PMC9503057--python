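"""Biweight chronologies, dendro statistics, crossdating, truncation."""

import numpy as np
import pandas as pd
import pytest

from ringclim import (
    Chronology,
    DailyClimate,
    IndexSeries,
    RingDataset,
    RingSeries,
    biweight_mean,
    build_chronology,
    crossdating_check,
    mean_sensitivity,
    rbar_and_eps,
    truncate_common_period,
)


def biweight_oracle(x, c=9.0, tol=1e-12, max_iter=500):
    """Independent iterative-reweighting implementation run to convergence."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return float(med)
    loc = med
    for _ in range(max_iter):
        u = (x - loc) / (c * mad)
        w = np.clip(1 - u**2, 0, None) ** 2
        new = np.sum(w * x) / np.sum(w)
        if abs(new - loc) < tol:
            break
        loc = new
    return float(loc)


def index_series(sid, first_year, values):
    v = np.asarray(values, dtype=float)
    return IndexSeries(sid, first_year, v, v.copy(), np.ones_like(v), 0)


class TestBiweight:
    @pytest.mark.parametrize(
        "sample,expected",
        [([1.0, 1.0, 1.0], 1.0), ([0.8, 1.0, 1.2], 1.0), ([2.0], 2.0), ([1.0, 3.0], 2.0)],
    )
    def test_symmetric_and_small_samples(self, sample, expected):
        assert biweight_mean(sample) == pytest.approx(expected)

    def test_resists_outlier_and_matches_oracle(self):
        sample = [1.0, 1.0, 1.0, 1.0, 10.0]
        got = biweight_mean(sample)
        assert 0.99 < got < 1.05
        assert got == pytest.approx(biweight_oracle(sample), abs=1e-6)

    def test_matches_oracle_on_random_samples(self, rng):
        for _ in range(25):
            sample = rng.normal(1.0, 0.3, rng.integers(3, 40))
            assert biweight_mean(sample) == pytest.approx(biweight_oracle(sample), abs=1e-6)

    def test_location_bounded_by_sample(self, rng):
        for _ in range(20):
            sample = rng.normal(0, 5, 15)
            m = biweight_mean(sample)
            assert sample.min() <= m <= sample.max()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            biweight_mean([])


class TestBuildChronology:
    def test_identical_series_reproduced(self):
        vals = np.array([1.0, 1.1, 0.9, 1.05])
        chron = build_chronology([index_series("A", 2000, vals), index_series("B", 2000, vals)])
        np.testing.assert_allclose(chron.index, vals)
        assert list(chron.sample_depth) == [2, 2, 2, 2]

    def test_disjoint_coverage_rejected(self):
        with pytest.raises(ValueError):
            build_chronology(
                [index_series("A", 1900, np.ones(10)), index_series("B", 1950, np.ones(10))]
            )

    def test_signal_recovery_improves_with_sample_size(self, rng):
        n_years = 80
        signal = rng.normal(1.0, 0.1, n_years)
        corrs = []
        for n_series in (3, 12, 48):
            series = [
                index_series(f"S{i}", 1900, signal + rng.normal(0, 0.3, n_years))
                for i in range(n_series)
            ]
            chron = build_chronology(series)
            corrs.append(np.corrcoef(chron.index, signal)[0, 1])
        assert corrs[0] < corrs[1] < corrs[2]


class TestMeanSensitivity:
    def test_closed_forms(self):
        assert mean_sensitivity(np.full(10, 2.0)) == 0.0
        assert mean_sensitivity(np.array([1.0, 3.0] * 5)) == pytest.approx(1.0)

    def test_scale_invariant(self, rng):
        x = np.abs(rng.normal(1, 0.2, 50)) + 0.1
        assert mean_sensitivity(7.3 * x) == pytest.approx(mean_sensitivity(x), rel=1e-12)

    def test_bi_scale_series_less_sensitive_than_trw_scale(self, rng):
        wiggle = rng.normal(0, 0.1, 60)
        trw_like = 1.0 + wiggle  # mean ~1 mm
        bi_like = 2.2 + wiggle  # same absolute SD on a BI-scale mean
        assert mean_sensitivity(bi_like) < mean_sensitivity(trw_like)

    def test_zero_sum_pair_rejected(self):
        with pytest.raises(ValueError):
            mean_sensitivity(np.array([1.0, 0.0, 0.0, 1.0]))


class TestRbarEps:
    def test_identical_series(self):
        vals = np.sin(np.arange(30)) + 2.0
        rbar, eps = rbar_and_eps(
            [index_series("A", 2000, vals), index_series("B", 2000, vals)]
        )
        assert rbar == pytest.approx(1.0)
        assert eps == pytest.approx(1.0)

    def test_eps_closed_form(self):
        # n_bar = 10, rbar = 0.3 -> eps = 3 / 3.7
        rbar, n_bar = 0.3, 10.0
        eps = n_bar * rbar / (n_bar * rbar + 1 - rbar)
        assert eps == pytest.approx(0.8108, abs=1e-4)

    def test_eps_monotone_in_rbar_and_depth(self):
        def eps(n, r):
            return n * r / (n * r + 1 - r)

        assert eps(10, 0.4) > eps(10, 0.3)
        assert eps(30, 0.3) > eps(10, 0.3)

    def test_window_restriction(self, rng):
        a = index_series("A", 1950, rng.normal(1, 0.1, 70))
        b = index_series("B", 1950, rng.normal(1, 0.1, 70))
        rbar_all, _ = rbar_and_eps([a, b])
        rbar_win, _ = rbar_and_eps([a, b], window=(1990, 2019))
        assert -1 <= rbar_all <= 1 and -1 <= rbar_win <= 1


class TestCrossdating:
    def _synchronized_dataset(self, rng, n=8, n_years=120):
        signal = rng.normal(0, 1, n_years)
        series = []
        for i in range(n):
            vals = np.abs(2.0 + 0.8 * signal + rng.normal(0, 0.4, n_years)) + 0.05
            series.append(RingSeries(f"S{i}", 1900, vals, "TRW"))
        return RingDataset(series=series, proxy_kind="TRW")

    def test_well_dated_series_passes(self, rng):
        ds = self._synchronized_dataset(rng)
        checks = crossdating_check(ds.series[0], ds)
        assert all(not c.flagged for c in checks)
        assert len(checks) == 3  # 120 years: starts 1900, 1925, 1950

    def test_shifted_series_flagged(self, rng):
        ds = self._synchronized_dataset(rng)
        shifted = RingSeries("S0", 1901, ds.series[0].values, "TRW")  # +1 year dating error
        peers = RingDataset(series=ds.series[1:] + [shifted], proxy_kind="TRW")
        checks = crossdating_check(shifted, peers)
        assert any(c.flagged for c in checks)

    def test_two_series_master_is_the_other(self, rng):
        vals = np.abs(rng.normal(2, 0.5, 80)) + 0.05
        a = RingSeries("A", 1900, vals, "TRW")
        b = RingSeries("B", 1900, vals * 1.3, "TRW")  # same pattern, different level
        ds = RingDataset(series=[a, b], proxy_kind="TRW")
        checks = crossdating_check(a, ds)
        for c in checks:
            assert c.r == pytest.approx(1.0, abs=1e-6)

    def test_short_series_single_truncated_segment(self, rng):
        ds = self._synchronized_dataset(rng)
        short = RingSeries("SH", 1900, ds.series[0].values[:30], "TRW")
        peers = RingDataset(series=ds.series[1:] + [short], proxy_kind="TRW")
        with pytest.warns(UserWarning, match="truncated"):
            checks = crossdating_check(short, peers)
        assert len(checks) == 1


class TestTruncation:
    def _climate(self, first="1978-01-01", last="2019-12-31"):
        dates = pd.date_range(first, last, freq="D")
        return DailyClimate("st", dates, np.full(len(dates), 5.0))

    def test_clips_to_common_period(self):
        chron = Chronology(np.arange(1885, 2020), np.ones(135), np.full(135, 10))
        out = truncate_common_period(chron, self._climate())
        assert (out.first_year, out.last_year) == (1978, 2019)
        assert len(out.years) == 42

    def test_covering_climate_leaves_unchanged(self):
        chron = Chronology(np.arange(1990, 2000), np.ones(10), np.full(10, 5))
        out = truncate_common_period(chron, self._climate("1950-01-01", "2020-12-31"))
        assert (out.first_year, out.last_year) == (1990, 1999)

    def test_disjoint_rejected(self):
        chron = Chronology(np.arange(1800, 1850), np.ones(50), np.full(50, 5))
        with pytest.raises(ValueError):
            truncate_common_period(chron, self._climate())

    def test_partial_first_year_excluded(self):
        chron = Chronology(np.arange(1970, 2020), np.ones(50), np.full(50, 5))
        out = truncate_common_period(chron, self._climate("1978-06-01", "2019-12-31"))
        assert out.first_year == 1979
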