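import numpy as np
import pandas as pd
import pytest

from sdindex import (
    DailySeries,
    Settings,
    doy_zscore,
    nrmse,
    r_squared,
    rolling_correlation_field,
    standardize,
)
from sdindex.errors import InvalidInputError, UndefinedNormalizationError
from sdindex.pipeline import SdiTable


def _daily(values, start="1950-01-01"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return DailySeries(idx, np.asarray(values, dtype=float))


class TestNrmse:
    def test_perfect_match(self):
        x = np.arange(10.0)
        assert nrmse(x, x) == 0.0

    def test_offset_by_one_sd(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=500)
        sim = obs + np.std(obs, ddof=1)
        assert nrmse(obs, sim) == pytest.approx(1.0)

    def test_too_few_pairs(self):
        with pytest.raises(InvalidInputError):
            nrmse([1.0], [1.0])

    def test_zero_variance_obs(self):
        with pytest.raises(UndefinedNormalizationError):
            nrmse([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_alternative_normalizations(self):
        obs = np.array([0.0, 10.0, 20.0])
        sim = obs + 2.0
        assert nrmse(obs, sim, "mean") == pytest.approx(0.2)
        assert nrmse(obs, sim, "range") == pytest.approx(0.1)

    def test_nan_pairs_dropped(self):
        obs = np.array([1.0, 2.0, np.nan, 4.0])
        sim = np.array([1.0, 2.0, 3.0, 4.0])
        assert nrmse(obs, sim) == 0.0


class TestRSquared:
    def test_perfect_affine(self):
        x = np.linspace(0, 1, 50)
        assert r_squared(x, 2.0 * x + 3.0) == pytest.approx(1.0)

    def test_sign_blind(self):
        x = np.linspace(0, 1, 50)
        assert r_squared(x, -x) == pytest.approx(1.0)

    def test_independent_noise(self):
        rng = np.random.default_rng(123)
        assert r_squared(rng.normal(size=10_000), rng.normal(size=10_000)) < 0.01

    def test_zero_variance(self):
        with pytest.raises(UndefinedNormalizationError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs(self):
        with pytest.raises(InvalidInputError):
            r_squared([1.0, 2.0], [1.0, 2.0])


class TestStandardize:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        out = standardize(_daily(rng.gamma(2, 3, 400)))
        vals = out.values[np.isfinite(out.values)]
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)
        assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        a = standardize(_daily(3.0 * x + 7.0)).values
        b = standardize(_daily(x)).values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_all_equal_rejected(self):
        with pytest.raises(UndefinedNormalizationError):
            standardize(_daily(np.full(100, 4.2)))

    def test_missing_preserved(self):
        vals = np.array([1.0, np.nan, 2.0, 3.0])
        out = standardize(_daily(vals))
        assert np.isnan(out.values[1])


class TestDoyZscore:
    @pytest.fixture
    def idx_20y(self):
        return pd.date_range("1990-01-01", "2009-12-31", freq="D")

    def test_pure_seasonal_cycle_all_missing(self, idx_20y):
        # a cycle that is a pure function of the calendar day (Feb 29 rides
        # with Feb 28) has zero within-day variance -> everything missing
        m = idx_20y.month.to_numpy()
        d = idx_20y.day.to_numpy()
        d_eff = np.where((m == 2) & (d == 29), 28, d)
        vals = np.sin(2 * np.pi * (m * 31 + d_eff) / 372.0)
        out = doy_zscore(DailySeries(idx_20y, vals))
        assert np.isnan(out.values).all()

    def test_noise_recovers_standard_moments(self, idx_20y):
        rng = np.random.default_rng(3)
        doy = idx_20y.dayofyear.to_numpy()
        vals = 10 * np.sin(2 * np.pi * doy / 365.25) + rng.normal(size=len(idx_20y))
        out = doy_zscore(DailySeries(idx_20y, vals))
        sel = (idx_20y.month == 6) & (idx_20y.day == 15)
        day_vals = out.values[sel]
        assert day_vals.mean() == pytest.approx(0.0, abs=1e-10)
        assert day_vals.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_seasonal_shift_invariance(self, idx_20y):
        rng = np.random.default_rng(4)
        noise = rng.normal(size=len(idx_20y))
        m = idx_20y.month.to_numpy()
        d = idx_20y.day.to_numpy()
        d_eff = np.where((m == 2) & (d == 29), 28, d)
        cycle = 5 * np.cos(2 * np.pi * (m * 31 + d_eff) / 372.0)
        a = doy_zscore(DailySeries(idx_20y, noise)).values
        b = doy_zscore(DailySeries(idx_20y, noise + cycle)).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_per_day_mean_is_zero(self, idx_20y):
        rng = np.random.default_rng(5)
        out = doy_zscore(DailySeries(idx_20y, rng.normal(size=len(idx_20y))))
        m = idx_20y.month.to_numpy()
        d = idx_20y.day.to_numpy()
        d_eff = np.where((m == 2) & (d == 29), 28, d)  # Feb 29 pools with 28
        frame = pd.DataFrame({"v": out.values, "m": m, "d": d_eff})
        means = frame.groupby(["m", "d"])["v"].mean().dropna()
        np.testing.assert_allclose(means.to_numpy(), 0.0, atol=1e-10)


class TestRollingCorrelationField:
    def _table(self, idx, columns):
        return SdiTable(pd.DataFrame(columns, index=idx))

    def test_identical_series_gives_unit_correlation(self):
        idx = pd.date_range("1990-01-01", "1999-12-31", freq="D")
        rng = np.random.default_rng(6)
        z = rng.normal(size=len(idx))
        resp = DailySeries(idx, z)
        table = self._table(idx, {"SPEI_30": z})
        field = rolling_correlation_field(resp, table, window_days=14)
        vals = field.frame.to_numpy()
        vals = vals[np.isfinite(vals)]
        assert len(vals) > 100
        np.testing.assert_allclose(vals, 1.0, atol=1e-10)

    def test_independent_noise_centered_on_zero(self):
        idx = pd.date_range("1970-01-01", "2009-12-31", freq="D")
        rng = np.random.default_rng(7)
        resp = DailySeries(idx, rng.normal(size=len(idx)))
        table = self._table(idx, {"SPEI_30": rng.normal(size=len(idx))})
        field = rolling_correlation_field(resp, table, window_days=14)
        vals = field.frame.to_numpy()
        vals = vals[np.isfinite(vals)]
        assert abs(np.mean(vals)) < 0.03
        assert (np.abs(vals) <= 1.0).all()

    def test_sparse_window_is_missing(self):
        idx = pd.date_range("1990-01-01", "1999-12-31", freq="D")
        rng = np.random.default_rng(8)
        z = rng.normal(size=len(idx))
        col = np.full(len(idx), np.nan)
        col[(idx.month == 6) & (idx.day == 1)] = z[(idx.month == 6) & (idx.day == 1)]
        col[(idx.month == 6) & (idx.day == 2)] = 0.5  # 2 valid calendar days only
        resp = DailySeries(idx, z)
        table = self._table(idx, {"SPEI_30": col})
        field = rolling_correlation_field(resp, table, window_days=3)
        # the June 2 cell pools days May 31..Jun 2: many pairs across years ->
        # defined; but a window fully inside missing columns stays missing
        assert np.isnan(field.frame.loc[(8, 15), "SPEI_30"])

    def test_window_too_small_rejected(self):
        idx = pd.date_range("1990-01-01", "1995-12-31", freq="D")
        resp = DailySeries(idx, np.zeros(len(idx)))
        table = self._table(idx, {"SPEI_30": np.zeros(len(idx))})
        with pytest.raises(InvalidInputError):
            rolling_correlation_field(resp, table, window_days=2)

    def test_season_rows_match_config(self):
        idx = pd.date_range("1990-01-01", "1999-12-31", freq="D")
        rng = np.random.default_rng(9)
        resp = DailySeries(idx, rng.normal(size=len(idx)))
        table = self._table(idx, {"SPEI_30": rng.normal(size=len(idx))})
        field = rolling_correlation_field(
            resp, table, settings=Settings(season_months=(6, 8))
        )
        months = field.frame.index.get_level_values("month").unique()
        assert sorted(months) == [6, 7, 8]
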