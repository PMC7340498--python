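"""From classified deaths to national mortality rates and totals.

The estimation chain mirrors standard verbal-autopsy practice: sampling
weights turn observed deaths into weighted cause fractions per stratum
(year, age band, ...); three-year backward moving averages smooth the
weighted death frequencies; zero-death strata are interpolated along year;
the fractions are multiplied into an externally estimated all-cause death
envelope to give cause-specific death totals; totals over person-years give
age-specific rates, which are age-standardized and cumulated into the risk
of dying of the cause before age 70.  Cubic regression splines smooth the
annual series and extrapolate it a few years beyond the observation window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from snakeburden.config import BANDS_UNDER_70


class ValidationError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cause fractions


def weighted_fractions(
    records: pd.DataFrame,
    is_cause: pd.Series | np.ndarray,
    strata: Sequence[str] = ("year", "age_band"),
    weight_col: str = "sampling_weight",
) -> pd.DataFrame:
    """Sampling-weighted cause fractions per stratum.

    Parameters
    ----------
    records
        One row per death, with the stratum columns and a positive weight.
    is_cause
        Boolean marker (aligned with ``records``) of deaths from the cause.

    Returns a table with weighted and unweighted numerators/denominators and
    the weighted fraction (NaN where a stratum has no deaths).
    """
    w = records[weight_col].to_numpy(float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValidationError("sampling weights must be positive and finite")
    df = records[list(strata)].copy()
    df["_w"] = w
    df["_cause_w"] = w * np.asarray(is_cause, dtype=float)
    df["_cause_n"] = np.asarray(is_cause, dtype=float)
    g = df.groupby(list(strata), as_index=False, observed=True).agg(
        weighted_cause=("_cause_w", "sum"),
        weighted_total=("_w", "sum"),
        cause_deaths=("_cause_n", "sum"),
        total_deaths=("_w", "size"),
    )
    g["fraction"] = np.where(
        g["weighted_total"] > 0, g["weighted_cause"] / g["weighted_total"], np.nan
    )
    return g


def moving_average(
    table: pd.DataFrame,
    window: int = 3,
    lag_weights: Sequence[float] | None = None,
    year_col: str = "year",
    group_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Backward moving average of weighted death frequencies.

    Numerator and denominator are smoothed separately (smoothing counts, not
    ratios, preserves envelope conservation); each year uses the current and
    previous ``window - 1`` years with the given lag weights (most recent
    first, default equal), renormalized over the years actually available at
    the edges.
    """
    if lag_weights is None:
        lag_weights = [1.0] * window
    lag_weights = list(lag_weights)
    if len(lag_weights) != window or any(w <= 0 for w in lag_weights):
        raise ValidationError("lag weights must be positive, one per lag")
    if group_cols is None:
        group_cols = [c for c in table.columns if c not in
                      {year_col, "weighted_cause", "weighted_total", "cause_deaths",
                       "total_deaths", "fraction", "imputed"}]

    def smooth(group: pd.DataFrame) -> pd.DataFrame:
        group = group.sort_values(year_col).reset_index(drop=True)
        years = group[year_col].to_numpy()
        num = group["weighted_cause"].to_numpy(float)
        den = group["weighted_total"].to_numpy(float)
        s_num, s_den = np.empty_like(num), np.empty_like(den)
        for i, y in enumerate(years):
            acc_n = acc_d = acc_w = 0.0
            for lag, lw in enumerate(lag_weights):
                j = np.flatnonzero(years == y - lag)
                if j.size:
                    acc_n += lw * num[j[0]]
                    acc_d += lw * den[j[0]]
                    acc_w += lw
            s_num[i] = acc_n / acc_w
            s_den[i] = acc_d / acc_w
        group["weighted_cause"] = s_num
        group["weighted_total"] = s_den
        return group

    if group_cols:
        parts = [smooth(g.copy()) for _, g in table.groupby(list(group_cols), observed=True)]
        out = pd.concat(parts, ignore_index=True)
    else:
        out = smooth(table.copy())
    out["fraction"] = np.where(
        out["weighted_total"] > 0, out["weighted_cause"] / out["weighted_total"], np.nan
    )
    return out


def interpolate_zero_strata(
    table: pd.DataFrame,
    year_col: str = "year",
    group_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fill missing stratum fractions by linear interpolation along year.

    A stratum-year with no observed deaths (fraction NaN) receives the linear
    interpolation of its neighbours within the stratum; leading/trailing
    gaps carry the nearest observed value.  Imputed cells are flagged.  A
    stratum whose entire series is missing is left missing.
    """
    if group_cols is None:
        group_cols = [c for c in table.columns if c not in
                      {year_col, "weighted_cause", "weighted_total", "cause_deaths",
                       "total_deaths", "fraction", "imputed"}]

    def fill(group: pd.DataFrame) -> pd.DataFrame:
        group = group.sort_values(year_col).reset_index(drop=True)
        frac = group["fraction"].astype(float)
        imputed = frac.isna()
        if imputed.all():
            group["imputed"] = imputed
            return group
        filled = frac.interpolate(method="linear", limit_direction="both")
        group["fraction"] = filled
        group["imputed"] = imputed
        return group

    if group_cols:
        parts = [fill(g.copy()) for _, g in table.groupby(list(group_cols), observed=True)]
        return pd.concat(parts, ignore_index=True)
    return fill(table.copy())


# ---------------------------------------------------------------------------
# envelope scaling and rates


def scale_to_envelope(
    table: pd.DataFrame,
    envelope: pd.DataFrame,
    on: Sequence[str] = ("year", "age_band"),
) -> pd.DataFrame:
    """Cause-specific death totals = stratum fraction x envelope deaths.

    The envelope carries all-cause death totals (and person-years) per
    stratum; missing envelope years are an error.  Summing the scaled
    all-cause fractions reproduces the envelope exactly by construction.
    """
    missing_years = set(table["year"]) - set(envelope["year"])
    if missing_years:
        raise AlignmentError(f"envelope missing years: {sorted(missing_years)}")
    env = envelope.rename(columns={"total_deaths": "envelope_deaths"})
    merged = table.merge(env, on=list(on), how="left", validate="many_to_one")
    if merged["envelope_deaths"].isna().any():
        bad = merged.loc[merged["envelope_deaths"].isna(), list(on)].drop_duplicates()
        raise AlignmentError(f"envelope missing strata: {bad.to_dict('records')[:5]}")
    merged["cause_deaths_scaled"] = merged["fraction"].fillna(0.0) * merged["envelope_deaths"]
    if "population" in merged.columns:
        merged["rate_per_100k"] = (
            merged["cause_deaths_scaled"] / merged["population"] * 1e5
        )
    return merged


def age_standardize(
    rates: pd.Series | dict[str, float], standard: pd.Series | dict[str, float]
) -> float:
    """Age-standardized rate: standard-weighted mean of age-specific rates.

    Weights are normalized to 1, so any positive rescaling of the standard
    population leaves the result unchanged.
    """
    rates = pd.Series(rates, dtype=float)
    standard = pd.Series(standard, dtype=float)
    if (standard <= 0).any() or not np.isfinite(standard).all():
        raise ValidationError("standard population weights must be positive and finite")
    missing = [b for b in standard.index if b not in rates.index]
    extra = [b for b in rates.index if b not in standard.index]
    if missing or extra:
        raise AlignmentError(
            f"age-band mismatch: missing rates for {missing}, unmatched rates {extra}"
        )
    w = standard / standard.sum()
    return float((rates.loc[w.index] * w).sum())


def risk_before_70(rates_per_100k: pd.Series | dict[str, float]) -> float:
    """Cumulative risk (%) of dying of the cause before 70.

    Additive approximation: 5 years x each 5-year band rate, summed over the
    14 bands 0-4 ... 65-69 (no exponential survival correction; at snakebite
    magnitudes the difference is below 0.001 percentage points).
    """
    rates = pd.Series(rates_per_100k, dtype=float)
    missing = [b for b in BANDS_UNDER_70 if b not in rates.index]
    if missing or len(rates.index) != len(BANDS_UNDER_70):
        raise ValidationError(
            f"need exactly the 14 bands 0-4..65-69; missing {missing}, got {len(rates)}"
        )
    return float(5.0 * rates.loc[list(BANDS_UNDER_70)].sum() / 1e5 * 100.0)


# ---------------------------------------------------------------------------
# spline smoothing / projection


@dataclass
class SplineTrend:
    """Cubic regression spline fit with linear out-of-range extrapolation."""

    years: np.ndarray
    fitted: np.ndarray
    knots: np.ndarray
    coef: np.ndarray
    _spline: object

    def predict(self, years: Sequence[float]) -> np.ndarray:
        years = np.asarray(years, dtype=float)
        lo, hi = self.years.min(), self.years.max()
        inside = np.clip(years, lo, hi)
        vals = self._spline(inside)
        dlo, dhi = self._spline(lo, 1), self._spline(hi, 1)
        vals = np.where(years < lo, self._spline(lo) + dlo * (years - lo), vals)
        vals = np.where(years > hi, self._spline(hi) + dhi * (years - hi), vals)
        return vals


def spline_trend(series: pd.Series, n_knots: int = 3) -> SplineTrend:
    """Fit a cubic regression spline to an annual series.

    Interior knots sit at year quantiles; outside the data range the terminal
    spline segment is continued linearly (value and first derivative at the
    boundary), which is how the projected years beyond the observation window
    are produced.
    """
    from scipy.interpolate import BSpline

    series = series.dropna().sort_index()
    years = series.index.to_numpy(float)
    y = series.to_numpy(float)
    if len(years) < n_knots + 4:
        raise ValidationError(
            f"{len(years)} years cannot support {n_knots} interior knots; "
            f"reduce n_knots to at most {max(len(years) - 4, 0)}"
        )
    interior = np.quantile(years, np.linspace(0, 1, n_knots + 2)[1:-1]) if n_knots else np.array([])
    t = np.concatenate([[years[0]] * 4, interior, [years[-1]] * 4])
    n_basis = len(t) - 4
    design = BSpline.design_matrix(years, t, k=3).toarray()
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    spline = BSpline(t, coef, 3)
    return SplineTrend(
        years=years,
        fitted=spline(years),
        knots=interior,
        coef=coef,
        _spline=spline,
    )


def hospital_split(total: float, in_hospital_fraction: float) -> tuple[float, float]:
    """Split a death total into (in-hospital, out-of-hospital)."""
    if not 0 <= in_hospital_fraction <= 1:
        raise ValidationError("in_hospital_fraction must be in [0, 1]")
    in_h = total * in_hospital_fraction
    return in_h, total - in_h


# ---------------------------------------------------------------------------
# assembled per-year rate series


def estimate_rate_series(
    deaths: pd.DataFrame,
    envelope: pd.DataFrame,
    standard: pd.Series | dict[str, float],
    review_results: dict | None = None,
    window: int = 3,
) -> pd.DataFrame:
    """End-to-end per-year rate series with lower/central/upper bounds.

    For each coding-agreement rule (lower: both coders X20; central: agreed
    plus review-confirmed; upper: any X20 code plus review-confirmed), run
    weighted fractions by year and age band, smooth with the backward moving
    average, interpolate zero strata, scale to the envelope, and derive
    age-specific rates, the age-standardized rate, the national death total
    (thousands) and the risk of dying before 70 (%).
    """
    from snakeburden import va_records

    cls = va_records.classify_records(deaths, review_results)
    c1 = deaths["coder1_icd10"].astype(str).str.upper()
    c2 = deaths["coder2_icd10"].astype(str).str.upper()
    agreed = (c1 == "X20") & (c2 == "X20")
    central = cls.isin([va_records.INCLUDED_AGREED, va_records.INCLUDED_AFTER_REVIEW])
    upper = central | ((c1 == "X20") | (c2 == "X20"))
    rules = {"lower": agreed, "central": central, "upper": upper}

    standard = pd.Series(standard, dtype=float)
    rows = []
    for bound, marker in rules.items():
        frac = weighted_fractions(deaths, marker, strata=("year", "age_band"))
        frac = moving_average(frac, window=window, group_cols=["age_band"])
        frac = interpolate_zero_strata(frac, group_cols=["age_band"])
        scaled = scale_to_envelope(frac, envelope)
        for year, g in scaled.groupby("year"):
            rates = g.set_index("age_band")["rate_per_100k"]
            rates = rates.reindex(standard.index).fillna(0.0)
            std_rate = age_standardize(rates, standard)
            risk = risk_before_70(rates.loc[list(BANDS_UNDER_70)])
            rows.append(
                {
                    "year": year,
                    "bound": bound,
                    "standardized_rate": std_rate,
                    "risk_before_70_pct": risk,
                    "deaths_thousands": g["cause_deaths_scaled"].sum() / 1e3,
                }
            )
    return pd.DataFrame(rows)
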