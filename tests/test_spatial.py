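"""National rate model, geostatistical RR model, grid prediction, thresholds."""

import numpy as np
import pandas as pd
import pytest

from snakeburden.config import BANDS_UNDER_70, SimulationConfig
from snakeburden import pipeline, spatial, synthetic


def _national_df(deaths, py, years=(2010,), bands=("30-34",), sexes=("male",)):
    rows = []
    for b in bands:
        for s in sexes:
            for y in years:
                rows.append({"age_band": b, "sex": s, "year": y,
                             "deaths": deaths, "person_years": py})
    return pd.DataFrame(rows)


class TestNationalRates:
    def test_single_cell_posterior_near_crude_rate(self):
        model = spatial.fit_national_rates(_national_df(10, 200_000))
        rate = model.rates["rate_per_100k"].iloc[0]
        assert rate == pytest.approx(5.0, rel=0.05)
        lo, hi = model.rates[["rate_lo", "rate_hi"]].iloc[0]
        assert lo < 5.0 < hi

    def test_doubling_offsets_halves_rates(self):
        m1 = spatial.fit_national_rates(_national_df(10, 200_000))
        m2 = spatial.fit_national_rates(_national_df(10, 400_000))
        r1 = m1.rates["rate_per_100k"].iloc[0]
        r2 = m2.rates["rate_per_100k"].iloc[0]
        assert r2 == pytest.approx(r1 / 2, rel=1e-3)

    def test_zero_exposure_cell_dropped_with_warning(self):
        df = _national_df(5, 100_000)
        df = pd.concat([df, _national_df(0, 0, bands=("40-44",))], ignore_index=True)
        with pytest.warns(UserWarning, match="zero exposure"):
            model = spatial.fit_national_rates(df)
        assert ("40-44", "male") not in model.cells

    def test_trend_recovered_across_replicates(self):
        """A -0.8%/year log-linear trend lies in its 95% interval in >=90%
        of replicates (Wald intervals from the Laplace covariance)."""
        true_trend = -0.008
        years = np.arange(2004, 2014)
        bands = list(BANDS_UNDER_70[:7])
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            rows = []
            for i, b in enumerate(bands):
                for s in ("male", "female"):
                    rate = 4e-5 * (1 + 0.1 * i)
                    for y in years:
                        py = 5e6
                        lam = py * rate * np.exp(true_trend * (y - 2010))
                        rows.append({"age_band": b, "sex": s, "year": y,
                                     "deaths": rng.poisson(lam), "person_years": py})
            model = spatial.fit_national_rates(pd.DataFrame(rows))
            lo, hi = model.trend_ci
            hits += lo <= true_trend <= hi
        assert hits >= 0.9 * n_rep

    def test_expected_deaths_roundtrip(self):
        model = spatial.fit_national_rates(_national_df(10, 200_000))
        exp = model.expected_deaths(_national_df(0, 200_000))
        assert exp[0] == pytest.approx(10.0, rel=0.05)


def _fit_sim(n_units=200, seed=3, spatial_sd=0.6, spatial_range=3.0, **kw):
    base = dict(n_units=n_units, seed=seed, years=tuple(range(2004, 2014)),
                other_cause_ratio=0.0, base_rate=30.0,
                spatial_sd=spatial_sd, spatial_range=spatial_range,
                mean_unit_population=5000)
    base.update(kw)
    cfg = SimulationConfig(**base)
    sim = synthetic.simulate(cfg)
    res = pipeline.run_spatial(sim["units"], sim["populations"], sim["deaths"],
                               cfg.years, review=sim["review"], grid_cell=2.0)
    return cfg, sim, res


class TestGeoRR:
    def test_null_truth_gives_flat_posterior(self):
        _, _, res = _fit_sim(seed=7, spatial_sd=0.0)
        ur = res["geo"].unit_rr()
        inside = ((ur["rr"] >= 0.9) & (ur["rr"] <= 1.1)).mean()
        assert inside >= 0.95

    def test_field_recovery_correlates_with_truth(self):
        _, sim, res = _fit_sim(n_units=300, seed=3)
        ur = res["geo"].unit_rr()
        truth = sim["surface"].log_rr_for(ur["unit_id"].to_numpy())
        assert np.corrcoef(np.log(ur["rr"]), truth)[0, 1] > 0.8
        assert res["geo"].sigma_spatial == pytest.approx(0.6, abs=0.25)

    def test_hyperparameters_within_credible_intervals(self):
        """Spatial SD and range of the generating field fall inside their
        approximate 95% intervals in most replicates."""
        hits_sigma = hits_range = 0
        n_rep = 6
        for rep in range(n_rep):
            _, _, res = _fit_sim(n_units=150, seed=100 + rep)
            ci = res["geo"].hyperparam_ci().set_index("param")
            s, r = ci.loc["sigma_spatial"], ci.loc["spatial_range"]
            hits_sigma += s["lo"] <= 0.6 <= s["hi"]
            hits_range += r["lo"] <= 3.0 <= r["hi"]
        assert hits_sigma + hits_range >= 0.8 * 2 * n_rep

    def test_exposure_scaling_approximate_invariance(self):
        """Multiplying populations and deaths by one constant leaves the
        posterior RR field essentially unchanged where the data dominate the
        prior; low-count units may shift slightly as shrinkage relaxes with
        the extra information."""
        _, sim, res = _fit_sim(n_units=120, seed=9, base_rate=60.0,
                               mean_unit_population=8000)
        base = res["geo"]
        scaled_data = pd.DataFrame({
            "unit_id": base.unit_ids,
            "lon": base.coords[:, 0], "lat": base.coords[:, 1],
            "deaths": base.y * 3, "expected": base.expected * 3,
        })
        for i, name in enumerate(base.covariate_names[1:], start=1):
            scaled_data[name] = base.X[:, i]
        refit = spatial.fit_geostatistical_rr(
            scaled_data, covariates=base.covariate_names[1:],
            optimize_hyperparams=False,
            init=(base.sigma_spatial, base.spatial_range, base.sigma_unit),
        )
        log_a = np.log(base.unit_rr()["rr"].to_numpy())
        log_b = np.log(refit.unit_rr()["rr"].to_numpy())
        diff = np.abs(log_b - log_a)
        assert np.median(diff) < 0.05
        assert np.corrcoef(log_a, log_b)[0, 1] > 0.99
        high_count = base.y >= np.median(base.y)
        assert diff[high_count].max() < 0.15

    def test_nonfinite_covariate_named(self):
        df = pd.DataFrame({"unit_id": ["a", "b", "c"], "lon": [0, 1, 2],
                           "lat": [0, 1, 2], "deaths": [1, 2, 3],
                           "expected": [1.0, 2.0, 3.0],
                           "altitude_km": [0.1, np.nan, 0.3]})
        with pytest.raises(spatial.ValidationError, match="altitude_km"):
            spatial.fit_geostatistical_rr(df)

    def test_zero_expected_with_deaths_rejected(self):
        df = pd.DataFrame({"unit_id": ["a"], "lon": [0], "lat": [0],
                           "deaths": [3], "expected": [0.0]})
        with pytest.raises(spatial.ValidationError):
            spatial.fit_geostatistical_rr(df)

    def test_mcmc_agrees_with_laplace(self):
        """Ensemble MCMC and the Laplace mode agree on posterior median RR
        within 10% on a small fixture."""
        cfg = SimulationConfig(n_units=30, seed=5, years=tuple(range(2004, 2014)),
                               other_cause_ratio=0.0, base_rate=40.0,
                               spatial_sd=0.5, spatial_range=3.0,
                               mean_unit_population=5000)
        sim = synthetic.simulate(cfg)
        res = pipeline.run_spatial(sim["units"], sim["populations"], sim["deaths"],
                                   cfg.years, review=sim["review"], grid_cell=3.0)
        lap = res["geo"].unit_rr()
        mc = spatial.sample_geostatistical_rr(res["geo"], n_steps=1200, n_burn=400,
                                              seed=0)
        rel = np.abs(mc["rr"].to_numpy() / lap["rr"].to_numpy() - 1)
        assert rel.max() < 0.10


class TestGridPrediction:
    def test_prediction_at_unit_locations_matches_unit_rr(self):
        _, _, res = _fit_sim(n_units=100, seed=13)
        geo = res["geo"]
        gc = pd.DataFrame({"row": range(geo.n_units), "col": 0,
                           "lon": geo.coords[:, 0], "lat": geo.coords[:, 1]})
        for i, name in enumerate(geo.covariate_names[1:], start=1):
            gc[name] = geo.X[:, i] * geo.cov_transform[name][1] + geo.cov_transform[name][0]
        pred = spatial.predict_rr_grid(geo, gc)
        ur = geo.unit_rr()
        np.testing.assert_allclose(pred["rr"], ur["rr"], rtol=1e-6)

    def test_missing_grid_covariates_raise_shape_error(self):
        _, _, res = _fit_sim(n_units=60, seed=15)
        gc = pd.DataFrame({"row": [0], "col": [0], "lon": [75.0], "lat": [20.0]})
        with pytest.raises(spatial.ShapeError):
            spatial.predict_rr_grid(res["geo"], gc)

    def test_fine_and_coarse_grids_agree_on_block_means(self):
        _, sim, res = _fit_sim(n_units=200, seed=3)
        fine = pipeline.make_grid_covariates(sim["units"], cell=1.0)
        pred = spatial.predict_rr_grid(res["geo"], fine)
        # block-average log RR over 4-degree quadrants vs direct coarse pred
        pred["qlon"] = (pred["lon"] // 4).astype(int)
        pred["qlat"] = (pred["lat"] // 4).astype(int)
        blocks = pred.groupby(["qlon", "qlat"])["rr"].apply(
            lambda r: np.log(r).mean()
        )
        coarse = pred.groupby(["qlon", "qlat"])["rr"].apply(
            lambda r: np.log(r.iloc[len(r) // 2])
        )
        # averages and central samples track the same field
        assert np.corrcoef(blocks, coarse)[0, 1] > 0.9


class TestAbsoluteRiskAndThresholds:
    surface = pd.DataFrame({"row": [0, 0, 1], "col": [0, 1, 0],
                            "lon": [70.0, 71.0, 70.0], "lat": [10.0, 10.0, 11.0],
                            "rr": [1.0, 1.5, 2.5]})

    def test_multiplicative_scaling(self):
        out = spatial.absolute_risk(self.surface, 0.4)
        np.testing.assert_allclose(out["abs_risk_pct"], [0.4, 0.6, 1.0])
        assert out["at_risk_ge_0.6pct"].tolist() == [False, True, True]
        assert out["at_risk_ge_1pct"].tolist() == [False, False, True]

    def test_cell_ratios_equal_rr_ratios(self):
        out = spatial.absolute_risk(self.surface, 0.37)
        ratio_abs = out["abs_risk_pct"].iloc[2] / out["abs_risk_pct"].iloc[0]
        assert ratio_abs == pytest.approx(2.5)

    def test_invalid_national_risk_rejected(self):
        with pytest.raises(spatial.ValidationError):
            spatial.absolute_risk(self.surface, 0.0)

    def test_population_at_risk_thresholds(self):
        out = spatial.absolute_risk(self.surface, 0.4)
        pop = self.surface[["row", "col", "lon", "lat"]].copy()
        pop["population"] = [700.0, 200.0, 100.0]
        par = spatial.population_at_risk(out, pop, thresholds=(0.0, 0.6, 1.0, 99.0))
        assert par.set_index("threshold_pct")["population"].tolist() == [
            1000.0, 300.0, 100.0, 0.0]
        # monotone non-increasing in the threshold
        assert (np.diff(par["population"]) <= 0).all()
        share = par.set_index("threshold_pct")["population_share"]
        assert share.loc[0.6] == pytest.approx(0.3)

    def test_constructed_exceedance_share_recovered_exactly(self):
        n = 100
        surf = pd.DataFrame({"row": np.arange(n), "col": 0,
                             "lon": 70.0 + 0.01 * np.arange(n), "lat": 10.0,
                             "rr": np.where(np.arange(n) < 10, 3.0, 1.0)})
        out = spatial.absolute_risk(surf, 0.4)
        pop = surf[["row", "col", "lon", "lat"]].copy()
        pop["population"] = 50.0
        par = spatial.population_at_risk(out, pop, thresholds=(1.0,))
        assert par["population_share"].iloc[0] == pytest.approx(0.10)

    def test_grid_mismatch_requires_resampling(self):
        out = spatial.absolute_risk(self.surface, 0.4)
        pop = pd.DataFrame({"row": [0, 0], "col": [0, 1],
                            "lon": [70.0, 71.0], "lat": [10.0, 10.0],
                            "population": [1.0, 2.0]})
        with pytest.raises(spatial.ShapeError):
            spatial.population_at_risk(out, pop)
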