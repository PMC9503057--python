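"""Bootstrap correlation, grid sweep, moving-window stability."""

import numpy as np
import pandas as pd
import pytest

from ringclim import (
    Chronology,
    DailyClimate,
    bootstrap_pearson,
    build_season_grid,
    correlate_grid,
    critical_r,
    moving_stability,
)


def chron(years, values):
    years = np.asarray(years)
    return Chronology(years, np.asarray(values, dtype=float), np.full(len(years), 20))


class TestBootstrapPearson:
    def test_perfect_correlation(self, rng):
        x = rng.normal(0, 1, 41)
        res = bootstrap_pearson(x, x.copy(), n_boot=500, seed=3)
        assert res.r == pytest.approx(1.0)
        assert res.significant and res.ci_low > 0

    def test_antisymmetry(self, rng):
        x = rng.normal(0, 1, 41)
        res = bootstrap_pearson(x, -x, n_boot=500, seed=3)
        assert res.r == pytest.approx(-1.0)
        assert res.ci_high < 0 and res.significant

    def test_affine_invariance_and_sign_flip(self, rng):
        x = rng.normal(0, 1, 41)
        y = 0.5 * x + rng.normal(0, 1, 41)
        base = bootstrap_pearson(x, y, n_boot=400, seed=9)
        scaled = bootstrap_pearson(x, 3.0 * y + 7.0, n_boot=400, seed=9)
        flipped = bootstrap_pearson(x, -2.0 * y + 1.0, n_boot=400, seed=9)
        assert scaled.r == pytest.approx(base.r, abs=1e-12)
        assert scaled.ci_low == pytest.approx(base.ci_low, abs=1e-12)
        assert flipped.r == pytest.approx(-base.r, abs=1e-12)

    def test_percentile_interval_brackets_r(self, rng):
        for seed in range(5):
            x = rng.normal(0, 1, 60)
            y = 0.4 * x + rng.normal(0, 1, 60)
            res = bootstrap_pearson(x, y, n_boot=800, seed=seed)
            assert -1 <= res.ci_low <= res.r <= res.ci_high <= 1

    def test_reproducible_given_seed(self, rng):
        x = rng.normal(0, 1, 41)
        y = rng.normal(0, 1, 41)
        a = bootstrap_pearson(x, y, n_boot=300, seed=11)
        b = bootstrap_pearson(x, y, n_boot=300, seed=11)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_pearson(np.ones(41), np.arange(41.0))
        with pytest.raises(ValueError):
            bootstrap_pearson(np.arange(20.0), np.arange(21.0))
        with pytest.raises(ValueError):
            bootstrap_pearson(np.arange(5.0), np.arange(5.0))


@pytest.fixture(scope="module")
def grid_and_years():
    rng = np.random.default_rng(5)
    years = np.arange(1979, 2020)
    dates = pd.date_range("1978-06-01", "2019-10-31", freq="D")
    temps = 5 - 11 * np.cos(2 * np.pi * (dates.dayofyear - 15) / 365.25)
    clim = DailyClimate("st", dates, temps + rng.normal(0, 3, len(dates)))
    return build_season_grid(clim, years), years


class TestCorrelateGrid:
    def test_signal_window_recovered(self, grid_and_years, rng):
        grid, years = grid_and_years
        true_start, true_width = 200, 60
        temp = grid.window_series(true_start, true_width)
        z = (temp - temp.mean()) / temp.std()
        x = z * 0.55 + rng.normal(0, np.sqrt(1 - 0.55**2), len(years))
        result = correlate_grid(chron(years, x), grid, n_boot=300, seed=1)
        assert result.best_cell is not None
        bs, bw = result.best_cell
        # the recovered best window overlaps the injected one
        assert bs <= true_start + true_width - 1 and true_start <= bs + bw - 1

    def test_grid_reproducible_and_consistent(self, grid_and_years, rng):
        grid, years = grid_and_years
        x = rng.normal(1, 0.1, len(years))
        a = correlate_grid(chron(years, x), grid, n_boot=200, seed=4)
        b = correlate_grid(chron(years, x), grid, n_boot=200, seed=4)
        np.testing.assert_array_equal(a.r, b.r)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)
        # significance flag is exactly "CI excludes zero"
        m = np.isfinite(a.r)
        assert np.array_equal(a.significant[m], (a.ci_low[m] > 0) | (a.ci_high[m] < 0))

    def test_constant_chronology_rejected(self, grid_and_years):
        grid, years = grid_and_years
        with pytest.raises(ValueError, match="variance"):
            correlate_grid(chron(years, np.ones(len(years))), grid, n_boot=100, seed=0)

    def test_year_mismatch_rejected(self, grid_and_years, rng):
        grid, years = grid_and_years
        bad = chron(years[:-1], rng.normal(1, 0.1, len(years) - 1))
        with pytest.raises(ValueError, match="match"):
            correlate_grid(bad, grid, n_boot=100, seed=0)


class TestMovingStability:
    def test_window_count_42_years(self, rng):
        years = np.arange(1978, 2020)
        x = rng.normal(1, 0.1, 42)
        y = rng.normal(0, 1, 42)
        res = moving_stability(chron(years, x), y, length=15, step=1)
        assert len(res.r) == 42 - 15 + 1 == 28

    def test_critical_r_n15(self):
        assert critical_r(15) == pytest.approx(0.514, abs=1e-3)

    def test_perfect_relation_all_significant(self, rng):
        years = np.arange(1980, 2010)
        x = rng.normal(0, 1, 30)
        res = moving_stability(chron(years, x), x.copy(), length=15)
        assert np.all(res.r == pytest.approx(1.0))
        assert res.significant.all()

    def test_too_short_rejected(self, rng):
        years = np.arange(2000, 2015)
        x = rng.normal(1, 0.1, 15)
        with pytest.raises(ValueError):
            moving_stability(chron(years, x), x, length=15)
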