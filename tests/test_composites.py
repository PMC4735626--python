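"""Composite means, ANOVA significance, curves, envelopes, moisture link."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from teleflux.anomaly import deseasonalize
from teleflux.composites import (PhaseCompositeModel, climate_composite_fields,
                                 composite_mean, composite_pairwise_difference,
                                 composite_significance, ensemble_envelope,
                                 flux_moisture_dependence, seasonal_flux_curves)
from teleflux.grid import STUDY_REGIONS, build_region_mask
from teleflux.series import AnnualAnomalySeries
from teleflux.synthetic import (SyntheticConfig, simulate_climate_stack,
                                simulate_flux_ensemble, simulate_mode_indices)
from teleflux.teleconnections import classify_phases, composite_membership, winter_index

from conftest import FAST_SYN


def series_of(values: dict, dataset="d0", region="europe"):
    return AnnualAnomalySeries(dataset=dataset, region=region,
                               values=pd.Series(values))


class TestCompositeMean:
    def test_constant_series(self):
        s = series_of({y: 0.7 for y in range(1982, 1992)})
        membership = {"NAO-EA-": [1983, 1984], "neutral": [1985], "NAO+EA+": []}
        out = composite_mean(s, membership)
        assert out["NAO-EA-"] == (pytest.approx(0.7), 2)
        assert out["NAO+EA+"][1] == 0

    def test_two_point_mean(self):
        s = series_of({1996: 0.3, 1997: 0.5})
        out = composite_mean(s, {"NAO-EA-": [1996, 1997]})
        assert out["NAO-EA-"][0] == pytest.approx(0.4)

    def test_weighted_means_reconstruct_grand_mean(self):
        rng = np.random.default_rng(0)
        years = np.arange(1982, 2013)
        s = series_of(dict(zip(years, rng.standard_normal(31))))
        from teleflux.series import WinterIndexSeries
        nao = WinterIndexSeries("NAO", pd.Series(rng.standard_normal(31), index=years))
        ea = WinterIndexSeries("EA", pd.Series(rng.standard_normal(31), index=years))
        m = composite_membership(classify_phases(nao, ea))
        out = composite_mean(s, m)
        num = sum(v * n for v, n in out.values() if n > 0)
        den = sum(n for _, n in out.values())
        assert num / den == pytest.approx(s.values.mean(), rel=1e-10)


class TestSignificance:
    def test_hand_computed_f(self):
        """mean .25, sd .1291, n 4 -> t = 3.873, F = t^2 = 15.0."""
        st = composite_significance([0.4, 0.1, 0.3, 0.2])
        assert st.F == pytest.approx(15.0, rel=1e-3)
        assert st.p == pytest.approx(2 * stats.t.sf(np.sqrt(15.0), 3), rel=1e-6)

    def test_zero_mean_pair(self):
        st = composite_significance([-0.3, 0.3])
        assert st.F == pytest.approx(0.0, abs=1e-12)
        assert st.p == pytest.approx(1.0)

    def test_degenerate_zero_variance(self):
        st = composite_significance([1.0, 1.0, 1.0, 1.0])
        assert st.degenerate.startswith("degenerate")
        assert st.p == 0.0

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(9) + 0.4
        assert composite_significance(v).p == pytest.approx(
            composite_significance(-v).p, rel=1e-12)

    def test_insufficient_years(self):
        with pytest.raises(ValueError, match="insufficient"):
            composite_significance([0.5])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_one_sample_t(self, seed):
        """F and p equal the textbook one-sample t-test against zero."""
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(rng.integers(3, 12)) + rng.normal(0, 0.5)
        st = composite_significance(v)
        t, p = stats.ttest_1samp(v, 0.0)
        assert st.F == pytest.approx(t**2, rel=1e-10)
        assert st.p == pytest.approx(p, rel=1e-10)


class TestPairwise:
    def test_identical_groups(self):
        F, p, flag = composite_pairwise_difference([0.1, 0.4, -0.2], [0.1, 0.4, -0.2])
        assert F == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_degenerate_separation(self):
        F, p, flag = composite_pairwise_difference([0.0, 0.0], [1.0, 1.0])
        assert flag.startswith("degenerate")
        assert p == 0.0

    @pytest.mark.parametrize("seed", range(30))
    def test_equals_pooled_t_squared(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(rng.integers(2, 9))
        b = rng.standard_normal(rng.integers(2, 9)) + 0.3
        F, p, _ = composite_pairwise_difference(a, b)
        t, pt = stats.ttest_ind(a, b, equal_var=True)
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_symmetry(self):
        a, b = [0.1, 0.3, 0.2], [-0.2, 0.0]
        assert composite_pairwise_difference(a, b)[0] == pytest.approx(
            composite_pairwise_difference(b, a)[0], rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            composite_pairwise_difference([0.1], [0.2, 0.3])


class TestModelFit:
    def _fixture(self, seed=3):
        rng = np.random.default_rng(seed)
        years = np.arange(1982, 2013)
        from teleflux.series import WinterIndexSeries
        nao = WinterIndexSeries("NAO", pd.Series(rng.standard_normal(31), index=years))
        ea = WinterIndexSeries("EA", pd.Series(rng.standard_normal(31), index=years))
        assignment = classify_phases(nao, ea)
        rows = []
        for ds, grp in (("inv00", "inversions"), ("dgvm00", "dgvms"), ("dgvm01", "dgvms")):
            for y in years:
                rows.append({"dataset": ds, "group": grp, "region": "europe",
                             "year": y, "value": rng.normal(0.05, 0.2)})
        return pd.DataFrame(rows), assignment

    def test_fit_shapes_and_summary(self):
        data, assignment = self._fixture()
        res = PhaseCompositeModel(data, assignment).fit()
        assert set(res.stats["composite"]) <= set(
            ["NAO+EA+", "NAO-EA-", "NAO+EA-", "NAO-EA+", "neutral"])
        assert {"inversions", "dgvms"} == set(res.stats["group"])
        text = res.summary()
        assert "one-sided" in text and "two-sided" in text

    def test_missing_columns_rejected(self):
        _, assignment = self._fixture()
        with pytest.raises(ValueError, match="missing columns"):
            PhaseCompositeModel(pd.DataFrame({"year": [1]}), assignment)

    def test_pooled_mean_matches_manual(self):
        data, assignment = self._fixture()
        res = PhaseCompositeModel(data, assignment).fit()
        m = composite_membership(assignment)
        sub = data[(data["group"] == "dgvms")
                   & data["year"].isin(m["neutral"])]["value"]
        got = res.composite_table("europe", "dgvms").loc["neutral", "mean"]
        assert got == pytest.approx(sub.mean(), rel=1e-12)


class TestClimateComposites:
    def test_injected_pattern_recovered(self, fast_config):
        """The composited temperature map correlates with the injected one."""
        cfg = fast_config
        nao, ea, truth = simulate_mode_indices(cfg)
        stack = simulate_climate_stack(cfg, truth, "T2M")
        anoms = deseasonalize(stack)
        membership = truth.composite_years()
        maps = climate_composite_fields(anoms, membership, "MaySep")
        from teleflux.synthetic import climate_pattern, COMPOSITE_PATTERN_SIGN
        pattern = climate_pattern(cfg, "T2M", cfg.make_flux_grid())
        for comp in ("NAO-EA-", "NAO+EA+"):
            if len(membership.get(comp, [])) < 2:
                continue
            sign = COMPOSITE_PATTERN_SIGN[comp]
            r = np.corrcoef((sign * pattern).ravel(), maps[comp].ravel())[0, 1]
            assert r > 0.9

    def test_zero_anomalies_zero_maps(self, fast_config):
        cfg = fast_config
        nao, ea, truth = simulate_mode_indices(cfg)
        stack = simulate_climate_stack(cfg, truth, "SD")
        stack.values[:] = 0.0
        anoms = deseasonalize(stack)
        maps = climate_composite_fields(anoms, truth.composite_years(), "DecApr")
        for comp, m in maps.items():
            ok = np.isfinite(m)
            assert np.allclose(m[ok], 0.0, atol=1e-12)

    def test_single_member_year_bitwise(self, fast_config):
        from teleflux.anomaly import seasonal_window_mean
        cfg = fast_config
        nao, ea, truth = simulate_mode_indices(cfg)
        anoms = deseasonalize(simulate_climate_stack(cfg, truth, "T2M"))
        y = int(truth.winter_phases.index[3])
        maps = climate_composite_fields(anoms, {"only": [y]}, "MaySep")
        assert np.array_equal(maps["only"], seasonal_window_mean(anoms, "MaySep", y))


class TestSeasonalCurves:
    def _world(self, fast_config):
        cfg = fast_config
        nao, ea, truth = simulate_mode_indices(cfg)
        members = simulate_flux_ensemble(cfg, truth, n_members=2)
        return cfg, truth, members

    def test_single_member_envelope_collapses(self, fast_config):
        cfg, truth, members = self._world(fast_config)
        mask = build_region_mask(STUDY_REGIONS["europe"], cfg.make_flux_grid())
        gpp = [deseasonalize(members[0]["GPP"])]
        reco = [deseasonalize(members[0]["RECO"])]
        curves = seasonal_flux_curves(gpp, reco, None, truth.composite_years(), mask)
        for comp, df in curves.curves.items():
            ok = df["gpp"].notna()
            assert np.allclose(df.loc[ok, "gpp_min"], df.loc[ok, "gpp"], atol=1e-12)
            assert np.allclose(df.loc[ok, "gpp_max"], df.loc[ok, "gpp"], atol=1e-12)

    def test_growing_season_enhancement(self):
        """GPP effects injected in May-Sep stay out of the cold months."""
        cfg = SyntheticConfig(seed=11, flux_noise_sd=0.0, cell_noise_sd=0.0,
                              **{k: v for k, v in FAST_SYN.items()
                                 if k not in ("n_members", "n_inversions")},
                              n_members=2, n_inversions=1)
        nao, ea, truth = simulate_mode_indices(cfg)
        members = simulate_flux_ensemble(cfg, truth, n_members=2)
        mask = build_region_mask(STUDY_REGIONS["europe"], cfg.make_flux_grid())
        gpp = [deseasonalize(m["GPP"]) for m in members]
        reco = [deseasonalize(m["RECO"]) for m in members]
        curves = seasonal_flux_curves(gpp, reco, None, truth.composite_years(), mask)
        df = curves.curves.get("NAO-EA-")
        if df is not None and df["gpp"].notna().any():
            assert df.loc[[6, 7], "gpp"].sum() > 0  # peak growing season
            assert np.all(np.abs(df.loc[[12, 1, 2], "gpp"]) < 1e-10)

    def test_nbp_linearity(self, fast_config):
        cfg, truth, members = self._world(fast_config)
        mask = build_region_mask(STUDY_REGIONS["europe"], cfg.make_flux_grid())
        gpp = [deseasonalize(m["GPP"]) for m in members]
        reco = [deseasonalize(m["RECO"]) for m in members]
        nbp = [deseasonalize(m["NBP"]) for m in members]
        membership = truth.composite_years()
        c_g = seasonal_flux_curves(gpp, reco, None, membership, mask)
        c_n = seasonal_flux_curves(nbp, reco, None, membership, mask)
        for comp in membership:
            g = c_g.curves[comp]
            n = c_n.curves[comp]
            ok = g["gpp"].notna()
            assert np.allclose(n.loc[ok, "gpp"],
                               g.loc[ok, "gpp"] - g.loc[ok, "reco"], atol=1e-10)

    def test_empty_ensemble_rejected(self, fast_config):
        mask = build_region_mask(STUDY_REGIONS["europe"], fast_config.make_flux_grid())
        with pytest.raises(ValueError, match="empty ensemble"):
            seasonal_flux_curves([], [], None, {}, mask)


class TestEnvelope:
    def test_single_dataset(self):
        s = series_of({2000: 0.5, 2001: -0.1})
        env = ensemble_envelope([s])
        assert (env["mean"] == env["min"]).all()
        assert (env["mean"] == env["max"]).all()

    def test_two_datasets(self):
        a = series_of({2000: 0.2}, dataset="a")
        b = series_of({2000: -0.4}, dataset="b")
        env = ensemble_envelope([a, b])
        assert env.loc[2000, "mean"] == pytest.approx(-0.1)
        assert env.loc[2000, "min"] == pytest.approx(-0.4)
        assert env.loc[2000, "max"] == pytest.approx(0.2)

    def test_staggered_spans(self):
        """Years outside a dataset's span do not enter its envelope."""
        a = series_of({2000: 1.0, 2001: 1.0, 2002: 1.0}, dataset="a")
        b = series_of({2000: -1.0, 2001: -1.0}, dataset="b")  # ends early
        env = ensemble_envelope([a, b])
        # oracle: explicit per-year filter
        for y in (2000, 2001, 2002):
            covering = [s for s in (a, b) if y in s.values.index]
            vals = [s.values[y] for s in covering]
            assert env.loc[y, "mean"] == pytest.approx(np.mean(vals))
            assert env.loc[y, "n_datasets"] == len(vals)


class TestMoistureDependence:
    def test_exact_linear(self):
        sw = series_of(dict(zip(range(2000, 2010), np.linspace(-2, 2, 10))))
        gpp = series_of({y: 2 * v for y, v in sw.values.items()})
        slope, r, p = flux_moisture_dependence(gpp, sw)
        assert slope == pytest.approx(2.0)
        assert r == pytest.approx(1.0)

    def test_independent_series_low_r(self):
        rng = np.random.default_rng(8)
        years = range(2000, 3000)
        sw = series_of(dict(zip(years, rng.standard_normal(1000))))
        gpp = series_of(dict(zip(years, rng.standard_normal(1000))))
        slope, r, p = flux_moisture_dependence(gpp, sw)
        assert abs(r) < 0.1

    def test_coupled_generator_recovery(self):
        """Injected soil-water -> GPP slope 1.5 recovered within 2 SE."""
        cfg = SyntheticConfig(seed=13, gpp_sw_slope=1.5, **FAST_SYN)
        nao, ea, truth = simulate_mode_indices(cfg)
        sw_stack = simulate_climate_stack(cfg, truth, "SW")  # records sw_annual
        members = simulate_flux_ensemble(cfg, truth, n_members=3)
        grid = cfg.make_flux_grid()
        mask = build_region_mask(STUDY_REGIONS["europe"], grid)
        from teleflux.anomaly import annual_regional_series
        sw = truth.sw_annual
        slopes = []
        for m in members:
            g = annual_regional_series(deseasonalize(m["GPP"]), mask, dataset="m")
            res = flux_moisture_dependence(
                g, AnnualAnomalySeries("sw", "europe", sw, units="% volume"))
            slope, r, p = res
            x = sw.to_numpy()
            resid_sd = np.std(g.values.to_numpy() - slope * x, ddof=2)
            se = resid_sd / (np.std(x) * np.sqrt(len(x)))
            assert abs(slope - 1.5) < 2 * max(se, 1e-6) + 0.05
            slopes.append(slope)
        assert np.mean(slopes) == pytest.approx(1.5, abs=0.1)

    def test_degenerate_regressor(self):
        sw = series_of({y: 1.0 for y in range(2000, 2010)})
        gpp = series_of({y: 0.1 * y for y in range(2000, 2010)})
        with pytest.raises(ValueError, match="degenerate regressor"):
            flux_moisture_dependence(gpp, sw)
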