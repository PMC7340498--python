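"""Cause fractions, envelope scaling, standardization, risk-to-70, splines."""

import numpy as np
import pandas as pd
import pytest

from snakeburden.config import BANDS_UNDER_70, SimulationConfig, standard_population_weights
from snakeburden import rates, synthetic


def _frac_table(**cols):
    base = {"year": [2001], "weighted_cause": [1.0], "weighted_total": [100.0]}
    base.update(cols)
    df = pd.DataFrame(base)
    df["fraction"] = df["weighted_cause"] / df["weighted_total"]
    return df


class TestWeightedFractions:
    def test_equal_weights_give_plain_fraction(self):
        rec = pd.DataFrame({"year": 2001, "age_band": "0-4",
                            "sampling_weight": 1.0}, index=range(100))
        is_cause = np.zeros(100, bool)
        is_cause[:2] = True
        out = rates.weighted_fractions(rec, is_cause)
        assert out["fraction"].iloc[0] == pytest.approx(0.02)

    def test_weights_shift_fraction(self):
        rec = pd.DataFrame({"year": [2001, 2001], "age_band": ["0-4", "0-4"],
                            "sampling_weight": [3.0, 1.0]})
        out = rates.weighted_fractions(rec, np.array([True, False]))
        assert out["fraction"].iloc[0] == pytest.approx(0.75)

    def test_nonpositive_weight_rejected(self):
        rec = pd.DataFrame({"year": [2001], "age_band": ["0-4"], "sampling_weight": [0.0]})
        with pytest.raises(rates.ValidationError):
            rates.weighted_fractions(rec, np.array([True]))


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        t = _frac_table(year=[2001, 2002, 2003], weighted_cause=[2.0] * 3,
                        weighted_total=[100.0] * 3)
        out = rates.moving_average(t, group_cols=[])
        assert np.allclose(out["fraction"], 0.02)

    def test_equal_lags_average_three_years(self):
        t = _frac_table(year=[2001, 2002, 2003], weighted_cause=[1.0, 2.0, 3.0],
                        weighted_total=[100.0] * 3)
        out = rates.moving_average(t, group_cols=[]).set_index("year")
        assert out.loc[2003, "fraction"] == pytest.approx(0.02)

    def test_first_year_keeps_own_value(self):
        t = _frac_table(year=[2001, 2002], weighted_cause=[1.0, 5.0],
                        weighted_total=[100.0] * 2)
        out = rates.moving_average(t, group_cols=[]).set_index("year")
        assert out.loc[2001, "fraction"] == pytest.approx(0.01)

    def test_nonpositive_lag_weight_rejected(self):
        with pytest.raises(rates.ValidationError):
            rates.moving_average(_frac_table(), lag_weights=[1, 0, 1], group_cols=[])

    def test_never_negative(self):
        rng = np.random.default_rng(0)
        t = _frac_table(year=list(range(2001, 2011)),
                        weighted_cause=rng.uniform(0, 5, 10),
                        weighted_total=rng.uniform(50, 150, 10))
        out = rates.moving_average(t, group_cols=[])
        assert (out["fraction"] >= 0).all()


class TestInterpolation:
    def test_linear_midpoint(self):
        t = _frac_table(year=[1, 2, 3], weighted_cause=[2, 0, 4],
                        weighted_total=[100, 0, 100])
        t.loc[1, "fraction"] = np.nan
        out = rates.interpolate_zero_strata(t, group_cols=[])
        assert out["fraction"].tolist() == pytest.approx([0.02, 0.03, 0.04])
        assert out["imputed"].tolist() == [False, True, False]

    def test_leading_gap_carried_back(self):
        t = _frac_table(year=[1, 2], weighted_cause=[0, 2], weighted_total=[0, 100])
        t.loc[0, "fraction"] = np.nan
        out = rates.interpolate_zero_strata(t, group_cols=[])
        assert out["fraction"].tolist() == pytest.approx([0.02, 0.02])

    def test_complete_table_unchanged(self):
        t = _frac_table(year=[1, 2], weighted_cause=[1, 2], weighted_total=[100, 100])
        out = rates.interpolate_zero_strata(t, group_cols=[])
        assert out["fraction"].tolist() == pytest.approx([0.01, 0.02])
        assert not out["imputed"].any()

    def test_fully_missing_stratum_left_missing(self):
        t = _frac_table(year=[1, 2], weighted_cause=[0, 0], weighted_total=[0, 0])
        t["fraction"] = np.nan
        out = rates.interpolate_zero_strata(t, group_cols=[])
        assert out["fraction"].isna().all()


class TestEnvelopeScaling:
    def test_fraction_times_envelope(self):
        t = _frac_table(year=[2001], weighted_cause=[0.5], weighted_total=[100.0])
        t["fraction"] = 0.005
        t["age_band"] = "0-4"
        env = pd.DataFrame({"year": [2001], "age_band": ["0-4"],
                            "total_deaths": [10_000_000.0], "population": [1e9]})
        out = rates.scale_to_envelope(t, env)
        assert out["cause_deaths_scaled"].iloc[0] == pytest.approx(50_000.0)

    def test_zero_fractions_give_zero_deaths(self):
        t = _frac_table(year=[2001], weighted_cause=[0.0])
        t["fraction"] = 0.0
        t["age_band"] = "0-4"
        env = pd.DataFrame({"year": [2001], "age_band": ["0-4"],
                            "total_deaths": [1e6]})
        assert rates.scale_to_envelope(t, env)["cause_deaths_scaled"].iloc[0] == 0.0

    def test_missing_envelope_year_named(self):
        t = _frac_table(year=[2001, 2002], weighted_cause=[1, 1],
                        weighted_total=[100, 100])
        t["age_band"] = "0-4"
        env = pd.DataFrame({"year": [2001], "age_band": ["0-4"], "total_deaths": [1e6]})
        with pytest.raises(rates.AlignmentError, match="2002"):
            rates.scale_to_envelope(t, env)

    def test_all_cause_fraction_conserves_envelope_exactly(self):
        rng = np.random.default_rng(1)
        years = list(range(2001, 2006))
        env = pd.DataFrame({"year": years, "age_band": "0-4",
                            "total_deaths": rng.uniform(1e5, 1e6, 5)})
        t = _frac_table(year=years, weighted_cause=[1.0] * 5, weighted_total=[1.0] * 5)
        t["age_band"] = "0-4"
        t["fraction"] = 1.0
        out = rates.scale_to_envelope(t, env)
        np.testing.assert_array_equal(
            out["cause_deaths_scaled"].to_numpy(), env["total_deaths"].to_numpy()
        )


class TestStandardization:
    def test_constant_profile_invariant(self):
        std = {b: w for b, w in zip("abcd", [1, 2, 3, 4])}
        assert rates.age_standardize({b: 5.0 for b in "abcd"}, std) == pytest.approx(5.0)

    def test_hand_weighted_average(self):
        assert rates.age_standardize({"a": 2.0, "b": 6.0}, {"a": 0.25, "b": 0.75}) == 5.0

    def test_rescaling_standard_is_invariant(self):
        r = {"a": 2.0, "b": 6.0}
        assert rates.age_standardize(r, {"a": 1, "b": 3}) == rates.age_standardize(
            r, {"a": 2, "b": 6}
        )

    def test_band_mismatch_listed(self):
        with pytest.raises(rates.AlignmentError, match="b"):
            rates.age_standardize({"a": 1.0}, {"a": 1, "b": 1})


class TestRiskBefore70:
    def test_zero_rates(self):
        assert rates.risk_before_70({b: 0.0 for b in BANDS_UNDER_70}) == 0.0

    def test_constant_five_per_100k(self):
        assert rates.risk_before_70({b: 5.0 for b in BANDS_UNDER_70}) == pytest.approx(0.35)

    def test_broad_band_reconstruction(self):
        # 0-14 at 4.5, 15-29 at 3.1, 30-69 at 5.8 per 100k
        per_band = {}
        for b in BANDS_UNDER_70:
            lo = int(b.split("-")[0])
            per_band[b] = 4.5 if lo < 15 else (3.1 if lo < 30 else 5.8)
        risk = rates.risk_before_70(per_band)
        assert risk == pytest.approx(0.346, abs=5e-4)

    def test_wrong_band_count_rejected(self):
        with pytest.raises(rates.ValidationError):
            rates.risk_before_70({"0-4": 5.0})


class TestSplineTrend:
    years = np.arange(2003, 2015)

    def test_exact_cubic_is_reproduced(self):
        x = self.years - 2003
        poly = 2.0 + 0.3 * x - 0.02 * x**2 + 0.001 * x**3
        fit = rates.spline_trend(pd.Series(poly, index=self.years))
        assert np.abs(fit.fitted - poly).max() < 1e-6

    def test_linear_series_extrapolates_linearly(self):
        lin = pd.Series(1.0 + 0.5 * (self.years - 2003), index=self.years)
        fit = rates.spline_trend(lin)
        np.testing.assert_allclose(
            fit.predict([2000, 2015, 2019]), [-0.5, 7.0, 9.0], atol=1e-8
        )

    def test_constant_series_constant_extrapolation(self):
        fit = rates.spline_trend(pd.Series(3.3, index=self.years))
        np.testing.assert_allclose(fit.predict([2000, 2019]), [3.3, 3.3], atol=1e-8)

    def test_too_few_years_guides_knot_reduction(self):
        with pytest.raises(rates.ValidationError, match="n_knots"):
            rates.spline_trend(pd.Series([1, 2, 3], index=[1, 2, 3]), n_knots=3)


def test_hospital_split_consistent_with_published_totals():
    in_h, out_h = rates.hospital_split(759.4, 154.2 / 759.4)
    assert in_h == pytest.approx(154.2)
    assert in_h + out_h == pytest.approx(759.4)
    assert rates.hospital_split(100.0, 0.0) == (0.0, 100.0)
    assert rates.hospital_split(100.0, 0.23) == pytest.approx((23.0, 77.0))


def test_rate_series_recovers_generator_truth(standard):
    """~10,000 snakebite deaths: standardized rate within 5%, risk-to-70
    within 10% of the generator's truth."""
    cfg = SimulationConfig(n_units=800, seed=17, years=tuple(range(2004, 2014)),
                           base_rate=9.6, mean_unit_population=13000,
                           other_cause_ratio=9.0, spatial_sd=0.3)
    sim = synthetic.simulate(cfg)
    n_snake = (sim["deaths"]["true_cause"] == "snakebite").sum()
    assert n_snake > 8000
    series = rates.estimate_rate_series(sim["deaths"], sim["envelope"], standard,
                                        sim["review"])
    central = series[series["bound"] == "central"]
    est_rate = central["standardized_rate"].mean()
    assert abs(est_rate / cfg.base_rate - 1) < 0.05

    mult = {b: m for b, m in zip(
        BANDS_UNDER_70,
        [__import__("snakeburden.config", fromlist=["age_rate_multipliers"])
         .age_rate_multipliers()[b] for b in BANDS_UNDER_70])}
    true_risk = rates.risk_before_70({b: cfg.base_rate * mult[b] for b in BANDS_UNDER_70})
    est_risk = central["risk_before_70_pct"].mean()
    assert abs(est_risk / true_risk - 1) < 0.10


def test_bounds_propagate_monotonically(small_sim, standard):
    series = rates.estimate_rate_series(small_sim["deaths"], small_sim["envelope"],
                                        standard, small_sim["review"])
    wide = series.pivot(index="year", columns="bound",
                        values="standardized_rate")
    assert (wide["lower"] <= wide["central"] + 1e-12).all()
    assert (wide["central"] <= wide["upper"] + 1e-12).all()
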