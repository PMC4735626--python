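"""Deseasonalization, integration and regional aggregation oracles."""

import numpy as np
import pandas as pd
import pytest

from teleflux.anomaly import (annual_integral, deseasonalize,
                              integrate_ndvi_annual, pdsi_regional_departure,
                              regional_integrate, seasonal_window_mean)
from teleflux.grid import (GridSpec, RegionBox, RegionMask, area_weights,
                           build_region_mask)
from teleflux.stacks import BiweeklyFieldStack, MonthlyFieldStack, month_index

from conftest import random_stack


def flux_stack(seed, n_months, grid=None, start="2000-01"):
    return random_stack(seed, n_months, variable="NBP", grid=grid,
                        start=start, units="PgC month-1 cell-1")


class TestDeseasonalize:
    def test_pure_cycle_removed(self):
        g = GridSpec.regular(40.0, 50.0, 0.0, 10.0, 5.0)
        cycle = np.sin(np.arange(12))[:, None, None] * np.ones((1,) + g.shape)
        vals = np.tile(cycle, (4, 1, 1))
        s = MonthlyFieldStack(variable="T2M", units="degC",
                              times=month_index("2000-01", 48), values=vals, grid=g)
        a = deseasonalize(s)
        assert np.allclose(a.values, 0.0, atol=1e-12)

    def test_constant_stack_zero_anomaly(self):
        s = random_stack(0, 36)
        s.values[:] = 7.5
        a = deseasonalize(s)
        assert np.allclose(a.values, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_two_pass_loop_oracle(self, seed):
        """Anomalies equal an explicit accumulate-then-subtract loop."""
        s = random_stack(seed, 36)
        a = deseasonalize(s)
        months = s.times.month
        for m in range(1, 13):
            sel = months == m
            clim = s.values[sel].mean(axis=0)
            for t in np.flatnonzero(sel):
                assert np.allclose(a.values[t], s.values[t] - clim, atol=1e-12)

    def test_residual_climatology_near_zero(self):
        s = random_stack(1, 60)
        a = deseasonalize(s)
        months = a.times.month
        sd = s.values.std()
        for m in range(1, 13):
            resid = a.values[months == m].mean(axis=0)
            assert np.max(np.abs(resid)) < 1e-10 * sd

    def test_short_base_period_rejected(self):
        s = random_stack(2, 12)
        with pytest.raises(ValueError, match="month"):
            deseasonalize(s)


class TestAnnualIntegral:
    def test_additivity(self):
        s = flux_stack(3, 24)
        a = deseasonalize(s)
        a.stack.values[:] = 0.25
        f = annual_integral(a, 2000)
        assert np.allclose(f, 3.0)

    def test_incomplete_year_rejected(self):
        from teleflux.anomaly import AnomalyStack, ClimatologyField
        s = flux_stack(4, 26)  # Jan 2000 .. Feb 2002
        a = AnomalyStack(stack=s, climatology=ClimatologyField(
            "NBP", np.zeros((12,) + s.grid.shape), (2000, 2001)))
        with pytest.raises(ValueError, match="incomplete year"):
            annual_integral(a, 2002)

    @pytest.mark.parametrize("seed", range(10))
    def test_naive_sum_oracle_and_linearity(self, seed):
        sx, sy = flux_stack(seed, 24), flux_stack(seed + 100, 24)
        ax, ay = deseasonalize(sx), deseasonalize(sy)
        fx = annual_integral(ax, 2001)
        # naive 12-term sum
        expect = np.zeros(sx.grid.shape)
        for m in range(1, 13):
            t = np.flatnonzero((ax.times.year == 2001) & (ax.times.month == m))[0]
            expect += ax.values[t]
        assert np.allclose(fx, expect, atol=1e-12)
        # linearity through the combined stack
        combo = sx.copy_with(values=2.0 * sx.values + 3.0 * sy.values)
        ac = deseasonalize(combo)
        assert np.allclose(annual_integral(ac, 2001),
                           2.0 * fx + 3.0 * annual_integral(ay, 2001), atol=1e-10)

    def test_mean_annual_anomaly_zero_over_base(self):
        s = flux_stack(6, 48)
        a = deseasonalize(s)
        fields = [annual_integral(a, y) for y in (2000, 2001, 2002, 2003)]
        assert np.allclose(np.mean(fields, axis=0), 0.0, atol=1e-12)


class TestSeasonalWindow:
    def test_december_attribution(self):
        """Dec-Apr of year y takes December from year y-1."""
        s = flux_stack(7, 36)
        a = deseasonalize(s)
        a.stack.values[:] = 0.0
        t_dec = np.flatnonzero((a.times.year == 2000) & (a.times.month == 12))[0]
        a.stack.values[t_dec] = 5.0
        f = seasonal_window_mean(a, "DecApr", 2001)
        assert np.allclose(f, 1.0)  # 5 / 5 window months
        assert np.allclose(seasonal_window_mean(a, "DecApr", 2002), 0.0)

    @pytest.mark.parametrize("seed,window", [(s, w) for s in range(5)
                                             for w in ("DecApr", "MaySep")])
    def test_naive_mean_oracle(self, seed, window):
        s = flux_stack(seed, 36)
        a = deseasonalize(s)
        months = {"DecApr": [(2000, 12), (2001, 1), (2001, 2), (2001, 3), (2001, 4)],
                  "MaySep": [(2001, 5), (2001, 6), (2001, 7), (2001, 8), (2001, 9)]}
        acc = np.zeros(s.grid.shape)
        for y, m in months[window]:
            t = np.flatnonzero((a.times.year == y) & (a.times.month == m))[0]
            acc += a.values[t]
        assert np.allclose(seasonal_window_mean(a, window, 2001), acc / 5, atol=1e-12)

    def test_missing_window_rejected(self):
        s = flux_stack(8, 24)
        a = deseasonalize(s)
        with pytest.raises(ValueError, match="incomplete window"):
            seasonal_window_mean(a, "DecApr", 2000)  # needs Dec 1999


class TestRegionalIntegrate:
    def test_uniform_intensive_mean(self):
        g = GridSpec.regular(40.0, 50.0, 0.0, 10.0, 2.5, 5.0)
        mask = build_region_mask(RegionBox("r", 2.0, 9.0, 41.0, 48.0), g)
        f = np.full(g.shape, 4.2)
        assert regional_integrate(f, mask, mode="mean") == pytest.approx(4.2)

    def test_single_cell_integral(self):
        g = GridSpec.regular(40.0, 50.0, 0.0, 10.0, 2.5, 5.0)
        w = np.zeros(g.shape)
        w[1, 1] = 1.0
        mask = RegionMask(grid=g, weights=w, name="cell")
        f = np.zeros(g.shape)
        f[1, 1] = 3.0
        assert regional_integrate(f, mask, mode="integral") == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_double_loop_oracle(self, seed):
        """Integral and mean match brute-force loops with cos-lat areas."""
        rng = np.random.default_rng(seed)
        g = GridSpec.regular(40.0, 50.0, 0.0, 25.0, 2.5, 5.0)
        f = rng.standard_normal(g.shape)
        w = rng.uniform(0, 1, g.shape)
        mask = RegionMask(grid=g, weights=w, name="rand")
        aw = area_weights(g)
        num = den = tot = 0.0
        for i in range(g.lat.size):
            for j in range(g.lon.size):
                tot += f[i, j] * w[i, j]
                num += f[i, j] * aw[i, j] * w[i, j]
                den += aw[i, j] * w[i, j]
        assert regional_integrate(f, mask, mode="integral") == pytest.approx(tot, rel=1e-12)
        assert regional_integrate(f, mask, mode="mean") == pytest.approx(num / den, rel=1e-10)

    def test_partition_sums_to_domain(self):
        g = GridSpec.regular(40.0, 50.0, 0.0, 10.0, 1.0)
        rng = np.random.default_rng(5)
        f = rng.standard_normal(g.shape)
        left = build_region_mask(RegionBox("l", 0.0, 5.0, 40.0, 50.0), g)
        right = build_region_mask(RegionBox("r", 5.0, 10.0, 40.0, 50.0), g)
        full = build_region_mask(RegionBox("f", 0.0, 10.0, 40.0, 50.0), g)
        s = (regional_integrate(f, left) + regional_integrate(f, right))
        assert s == pytest.approx(regional_integrate(f, full), rel=1e-10)

    def test_empty_region(self):
        g = GridSpec.regular(40.0, 50.0, 0.0, 10.0, 2.5)
        mask = RegionMask(grid=g, weights=np.zeros(g.shape), name="empty")
        with pytest.raises(ValueError, match="empty region"):
            regional_integrate(np.ones(g.shape), mask)


class TestNDVI:
    def grid(self):
        return GridSpec.regular(40.0, 50.0, 0.0, 10.0, 5.0)

    def stack(self, values, years=(2000, 2001, 2002)):
        return BiweeklyFieldStack(years=np.array(years), values=values,
                                  grid=self.grid())

    def test_identical_years_zero_anomaly(self):
        g = self.grid()
        one_year = np.random.default_rng(0).uniform(0, 1, (1, 24) + g.shape)
        vals = np.tile(one_year, (3, 1, 1, 1))
        years, anoms = integrate_ndvi_annual(self.stack(vals))
        assert np.allclose(anoms, 0.0, atol=1e-12)

    def test_single_perturbed_year_closed_form(self):
        """+delta per sample in one year -> anomaly 24*delta*(1 - 1/n)."""
        g = self.grid()
        delta = 0.01
        vals = np.full((4, 24) + g.shape, 0.5)
        vals[1] += delta
        years, anoms = integrate_ndvi_annual(self.stack(vals, (2000, 2001, 2002, 2003)))
        expect = 24 * delta * (1 - 0.25)
        assert np.allclose(anoms[1], expect, atol=1e-12)
        assert np.allclose(anoms[0], -24 * delta * 0.25, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_naive_24_term_sums(self, seed):
        g = self.grid()
        rng = np.random.default_rng(seed)
        vals = rng.uniform(-0.2, 0.9, (3, 24) + g.shape)
        years, anoms = integrate_ndvi_annual(self.stack(vals))
        sums = np.zeros((3,) + g.shape)
        for y in range(3):
            for s in range(24):
                sums[y] += vals[y, s]
        expect = sums - sums.mean(axis=0)
        assert np.allclose(anoms, expect, atol=1e-12)

    def test_incomplete_year_rejected(self):
        g = self.grid()
        vals = np.full((2, 24) + g.shape, 0.3)
        mask = np.zeros_like(vals, dtype=bool)
        mask[1, 5, 0, 0] = True
        st = BiweeklyFieldStack(years=np.array([2000, 2001]), values=vals,
                                grid=g, mask=mask)
        with pytest.raises(ValueError, match="incomplete year"):
            integrate_ndvi_annual(st)


class TestPDSIDeparture:
    def test_time_constant_field(self):
        s = random_stack(0, 24)
        s.values[:] = 2.0
        mask = build_region_mask(RegionBox("r", 2.0, 9.0, 41.0, 48.0), s.grid)
        d = pdsi_regional_departure(s, mask)
        assert np.allclose(d.to_numpy(), 0.0, atol=1e-12)

    def test_spatially_uniform_collapse(self):
        s = random_stack(1, 24)
        p = np.sin(np.arange(24) / 3.0)
        s.values[:] = p[:, None, None]
        mask = build_region_mask(RegionBox("r", 2.0, 9.0, 41.0, 48.0), s.grid)
        d = pdsi_regional_departure(s, mask)
        assert np.allclose(d.to_numpy(), p - p.mean(), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_loop_oracle(self, seed):
        s = random_stack(seed, 18)
        mask = build_region_mask(RegionBox("r", 2.0, 9.0, 41.0, 48.0), s.grid)
        d = pdsi_regional_departure(s, mask)
        aw = area_weights(s.grid) * mask.weights
        series = []
        for t in range(18):
            num = den = 0.0
            for i in range(s.grid.lat.size):
                for j in range(s.grid.lon.size):
                    num += s.values[t, i, j] * aw[i, j]
                    den += aw[i, j]
            series.append(num / den)
        series = np.array(series)
        assert np.allclose(d.to_numpy(), series - series.mean(), atol=1e-10)
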