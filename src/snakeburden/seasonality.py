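"""Seasonal Poisson modelling of daily deaths and altitude profiles.

Daily death counts pooled by day-of-year (a composite year across all study
years, leap days folded into February 28) are modelled with a Poisson GLM on
harmonic terms of day-of-year.  Because the GLM with canonical log link and
an intercept preserves the fitted total, the predicted annual curve sums to
the observed deaths (optionally rescaled to national totals).  Crude death
rates by altitude aggregate unit-level deaths and person-years into 100 m
elevation bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

DAYS = 365
MONSOON_START_DOY = 152  # June 1 (non-leap)
MONSOON_END_DOY = 273    # September 30


class ValidationError(ValueError):
    pass


class DegenerateFitError(ValueError):
    pass


@dataclass
class SeasonalModel:
    """Fitted cyclic Poisson model of daily deaths."""

    intercept: float
    harmonics: int
    coef: np.ndarray          # [intercept, sin1, cos1, sin2, cos2, ...]
    coef_se: np.ndarray
    curve: np.ndarray         # expected deaths for days 1..365
    peak_day: int
    trough_day: int
    peak_value: float
    trough_value: float
    is_flat: bool

    @property
    def peak_trough_ratio(self) -> float:
        return float(self.peak_value / self.trough_value)


def _fold_day_of_year(dates: pd.Series) -> np.ndarray:
    """Day of year 1..365 with Feb 29 folded into Feb 28 (day 59)."""
    dates = pd.to_datetime(dates)
    doy = dates.dt.dayofyear.to_numpy().copy()
    leap = dates.dt.is_leap_year.to_numpy()
    after_feb28 = leap & (doy >= 60)
    doy[after_feb28] -= 1
    return doy


def _harmonic_design(days: np.ndarray, harmonics: int) -> np.ndarray:
    cols = [np.ones_like(days, dtype=float)]
    for h in range(1, harmonics + 1):
        angle = 2 * np.pi * h * days / DAYS
        cols.extend([np.sin(angle), np.cos(angle)])
    return np.column_stack(cols)


def daily_counts(dates: pd.Series) -> np.ndarray:
    """Pooled composite-year counts for days 1..365."""
    doy = _fold_day_of_year(dates)
    return np.bincount(doy, minlength=DAYS + 1)[1:].astype(float)


def fit_seasonal(
    dates: pd.Series | None = None,
    counts: np.ndarray | None = None,
    harmonics: int = 2,
    scale_to_total: float | None = None,
) -> SeasonalModel:
    """Fit the harmonic Poisson model of daily mortality.

    Parameters
    ----------
    dates
        Death dates (pooled across years into a composite year), or
    counts
        365 pre-aggregated daily counts.
    harmonics
        Number of sine/cosine pairs (default 2: annual + semi-annual).
    scale_to_total
        If given, rescale the predicted curve so it sums to this annual
        total (e.g. national deaths per year estimated elsewhere), keeping
        the within-year shape from the survey.
    """
    if counts is None:
        if dates is None:
            raise ValidationError("provide dates or counts")
        counts = daily_counts(dates)
    counts = np.asarray(counts, dtype=float)
    if len(counts) != DAYS:
        raise ValidationError(f"need {DAYS} daily counts, got {len(counts)}")
    if counts.sum() == 0:
        raise DegenerateFitError("all daily counts are zero; cannot fit seasonality")
    days = np.arange(1, DAYS + 1)
    X = _harmonic_design(days, harmonics)
    fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    curve = np.asarray(fit.predict(X))
    if scale_to_total is not None:
        curve = curve * (scale_to_total / curve.sum())
    peak = int(days[np.argmax(curve)])
    trough = int(days[np.argmin(curve)])
    ratio = curve.max() / curve.min()
    return SeasonalModel(
        intercept=float(fit.params[0]),
        harmonics=harmonics,
        coef=np.asarray(fit.params),
        coef_se=np.asarray(fit.bse),
        curve=curve,
        peak_day=peak,
        trough_day=trough,
        peak_value=float(curve.max()),
        trough_value=float(curve.min()),
        is_flat=bool(ratio < 1.02),
    )


def monsoon_share(dates: pd.Series) -> tuple[float, pd.DataFrame]:
    """Share of deaths during the southwest monsoon (June 1 - September 30).

    Returns the pooled share and a per-year breakdown.
    """
    dates = pd.to_datetime(dates)
    doy = _fold_day_of_year(dates)
    in_monsoon = (doy >= MONSOON_START_DOY) & (doy <= MONSOON_END_DOY)
    per_year = (
        pd.DataFrame({"year": dates.dt.year, "monsoon": in_monsoon})
        .groupby("year")
        .agg(deaths=("monsoon", "size"), monsoon_deaths=("monsoon", "sum"))
        .assign(share=lambda d: d["monsoon_deaths"] / d["deaths"])
        .reset_index()
    )
    return float(in_monsoon.mean()), per_year


def altitude_profile(
    deaths: pd.DataFrame,
    units: pd.DataFrame,
    n_years: int,
    bin_m: float = 100.0,
) -> pd.DataFrame:
    """Crude death rates by altitude bin.

    Deaths are assigned their sampling unit's altitude; person-years are
    unit population x ``n_years``.  Returns per-bin deaths, person-years,
    crude rate per 100,000 and the cumulative share of deaths below each
    bin's upper edge.
    """
    alt = units.set_index("unit_id")["altitude_m"]
    if (alt < 0).any():
        raise ValidationError("negative altitude in units table")
    pop = units.set_index("unit_id")["population"]
    death_alt = alt.loc[deaths["unit_id"]].to_numpy()
    max_alt = float(alt.max())
    edges = np.arange(0.0, max_alt + bin_m, bin_m)
    if edges[-1] <= max_alt:
        edges = np.append(edges, edges[-1] + bin_m)
    death_bin = np.digitize(death_alt, edges) - 1
    unit_bin = np.digitize(alt.to_numpy(), edges) - 1
    n_bins = len(edges) - 1
    deaths_per_bin = np.bincount(death_bin, minlength=n_bins)[:n_bins]
    py_per_bin = np.bincount(unit_bin, weights=pop.to_numpy() * n_years, minlength=n_bins)[:n_bins]
    profile = pd.DataFrame(
        {
            "bin_low_m": edges[:-1],
            "bin_high_m": edges[1:],
            "deaths": deaths_per_bin,
            "person_years": py_per_bin,
        }
    )
    profile["rate_per_100k"] = np.where(
        profile["person_years"] > 0,
        profile["deaths"] / profile["person_years"] * 1e5,
        np.nan,
    )
    profile["cumulative_death_share"] = profile["deaths"].cumsum() / max(
        profile["deaths"].sum(), 1
    )
    return profile
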