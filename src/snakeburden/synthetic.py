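"""Synthetic survey generator with a known ground truth.

Emulates the observation process of a nationally representative
verbal-autopsy mortality survey: geocoded sampling units in rural/urban
strata with demographic and environmental covariates, a spatially correlated
relative-risk field, monsoon-peaked seasonality of snakebite deaths,
dual-physician ICD-10 coding with imperfect agreement, interleaved
non-snakebite deaths, and literature-style bite/death study tables.  Every
downstream estimator in the package can be validated against the generator's
recorded truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.gaussian_process.kernels import Matern

from snakeburden.config import (
    AGE_BANDS,
    AGE_BAND_LOWER,
    OTHER_ICD10_CODES,
    ConfigurationError,
    SimulationConfig,
    age_rate_multipliers,
    standard_population_weights,
)
from snakeburden.grids import Grid

DAYS_IN_YEAR = 365


class AlignmentError(ValueError):
    """Units and true surface do not refer to the same unit ids."""


@dataclass
class TrueSurface:
    """Ground truth underlying a simulated survey.

    Attributes
    ----------
    grid
        Log relative risk on a regular lon-lat grid (spatial field only,
        normalized so the population-weighted mean unit RR is exactly 1).
    unit_ids
        Unit ids aligned with ``unit_log_rr``.
    unit_log_rr
        Realized spatial log relative risk at each sampling unit.
    seasonal
        365 daily multipliers with mean 1 describing within-year seasonality.
    """

    grid: Grid
    unit_ids: np.ndarray
    unit_log_rr: np.ndarray
    seasonal: np.ndarray

    def log_rr_for(self, unit_ids: np.ndarray) -> np.ndarray:
        lookup = pd.Series(self.unit_log_rr, index=self.unit_ids)
        missing = set(np.asarray(unit_ids)) - set(self.unit_ids)
        if missing:
            raise AlignmentError(f"units missing from true surface: {sorted(missing)[:5]}")
        return lookup.loc[np.asarray(unit_ids)].to_numpy()


def seasonal_curve(amplitude: float, peak_day: int = 196) -> np.ndarray:
    """Daily multipliers exp(A cos(2*pi*(d - peak)/365)), normalized to mean 1."""
    days = np.arange(1, DAYS_IN_YEAR + 1)
    curve = np.exp(amplitude * np.cos(2 * np.pi * (days - peak_day) / DAYS_IN_YEAR))
    return curve / curve.mean()


def monsoon_share_of_curve(curve: np.ndarray) -> float:
    """Share of the annual curve falling on June 1 - September 30 (days 152-273)."""
    return float(curve[151:273].sum() / curve.sum())


def amplitude_for_monsoon_share(share: float, peak_day: int = 196) -> float:
    """Solve for the sinusoid amplitude giving a target June-September share.

    The flat curve gives 122/365 ~ 0.334; shares up to ~0.95 are attainable
    with a mid-July peak.
    """
    from scipy.optimize import brentq

    flat = 122 / 365
    if not flat - 1e-9 <= share < 0.96:
        raise ConfigurationError(
            f"monsoon share {share} not attainable with a single annual sinusoid"
        )
    if abs(share - flat) < 1e-9:
        return 0.0
    return float(
        brentq(
            lambda a: monsoon_share_of_curve(seasonal_curve(a, peak_day)) - share,
            1e-8,
            6.0,
        )
    )


def generate_units(config: SimulationConfig) -> pd.DataFrame:
    """Generate the sampling-unit table.

    Units are scattered uniformly over the configured lon-lat rectangle.
    Altitude is log-normal (median ~200 m) with a smooth north-south trend,
    temperature follows a latitude gradient minus a 6.5 degC/km lapse rate,
    and rural female illiteracy is Beta-distributed.  Unit populations are
    log-normal around ``mean_unit_population``.
    """
    rng = config.rng()
    n = config.n_units
    lon = rng.uniform(*config.lon_range, n)
    lat = rng.uniform(*config.lat_range, n)
    rural = rng.random(n) < config.rural_share
    # smooth northward rise plus log-normal local relief
    trend = 40.0 * np.clip(lat - config.lat_range[0], 0, None)
    altitude = trend * rng.uniform(0.0, 1.0, n) + np.exp(rng.normal(np.log(150.0), 0.9, n))
    temperature = 29.0 - 0.25 * (lat - config.lat_range[0]) - 6.5 * altitude / 1000.0
    temperature += rng.normal(0.0, 1.0, n)
    illiteracy = rng.beta(4.0, 4.0, n)
    illiteracy = np.where(rural, illiteracy, illiteracy * 0.6)
    population = np.exp(rng.normal(np.log(config.mean_unit_population), 0.4, n))
    units = pd.DataFrame(
        {
            "unit_id": [f"U{i:05d}" for i in range(n)],
            "lon": lon,
            "lat": lat,
            "rural": rural,
            "altitude_m": altitude,
            "temperature_c": temperature,
            "female_illiteracy": illiteracy,
            "population": population,
            "sampling_weight": np.where(rural, config.rural_weight, config.urban_weight),
        }
    )
    return units


def age_sex_population(units: pd.DataFrame) -> pd.DataFrame:
    """Expand unit totals to a long age-sex population table.

    The bundled standard-population pyramid is applied to every unit with an
    even sex split, mirroring a survey in which all units of a stratum share
    one census age structure.
    """
    shares = standard_population_weights()
    frames = []
    for band in AGE_BANDS:
        for sex in ("male", "female"):
            frames.append(
                pd.DataFrame(
                    {
                        "unit_id": units["unit_id"],
                        "age_band": band,
                        "sex": sex,
                        "population": units["population"] * shares[band] * 0.5,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def covariate_log_rr(units: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """Population-weight-centred covariate contribution to unit log RR."""
    design = {
        "rural": units["rural"].to_numpy(float),
        "altitude_km": units["altitude_m"].to_numpy(float) / 1000.0,
        "temperature_c": units["temperature_c"].to_numpy(float),
        "female_illiteracy": units["female_illiteracy"].to_numpy(float),
    }
    w = units["population"].to_numpy(float)
    log_rr = np.zeros(len(units))
    for name, beta in config.covariate_effects.items():
        x = design[name]
        log_rr += beta * (x - np.average(x, weights=w))
    return log_rr


def generate_true_surface(
    units: pd.DataFrame, config: SimulationConfig, grid_shape: tuple[int, int] = (30, 30)
) -> TrueSurface:
    """Draw the spatial log-RR field and the seasonal curve.

    The field is a Gaussian process with Matern covariance (smoothness 1)
    sampled on a coarse grid and bilinearly interpolated to the units, then
    normalized so the population-weighted mean relative risk over units is
    exactly 1 (keeping ``base_rate`` the national rate).
    """
    rng = np.random.default_rng(config.seed + 1)
    nrow, ncol = grid_shape
    lon0, lon1 = config.lon_range
    lat0, lat1 = config.lat_range
    cell_lon = (lon1 - lon0) / max(ncol - 1, 1)
    cell_lat = (lat1 - lat0) / max(nrow - 1, 1)
    cell = max(cell_lon, cell_lat)
    lons = lon0 + cell * np.arange(ncol)
    lats = lat0 + cell * np.arange(nrow)
    if config.spatial_sd > 0:
        gx, gy = np.meshgrid(lons, lats)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        kernel = Matern(length_scale=config.spatial_range, nu=1.0)
        cov = config.spatial_sd**2 * kernel(pts)
        cov[np.diag_indices_from(cov)] += 1e-8
        field = np.linalg.cholesky(cov) @ rng.standard_normal(len(pts))
        values = field.reshape(nrow, ncol)
    else:
        values = np.zeros((nrow, ncol))
    grid = Grid(lon0=lon0, lat0=lat0, cell=cell, values=values)
    unit_log_rr = grid.interpolate_to(units["lon"].to_numpy(), units["lat"].to_numpy())
    w = units["population"].to_numpy(float)
    log_norm = np.log(np.average(np.exp(unit_log_rr), weights=w))
    unit_log_rr = unit_log_rr - log_norm
    grid = Grid(lon0=lon0, lat0=lat0, cell=cell, values=values - log_norm)
    seasonal = seasonal_curve(config.seasonal_amplitude, config.peak_day)
    return TrueSurface(
        grid=grid,
        unit_ids=units["unit_id"].to_numpy(),
        unit_log_rr=unit_log_rr,
        seasonal=seasonal,
    )


def expected_snakebite_deaths(
    units: pd.DataFrame, surface: TrueSurface, config: SimulationConfig
) -> pd.DataFrame:
    """Expected snakebite deaths per unit x age band x sex x year.

    lambda = person-years x base_rate x age multiplier x unit RR x trend.
    """
    mult = age_rate_multipliers()
    shares = standard_population_weights()
    log_rr = surface.log_rr_for(units["unit_id"].to_numpy()) + covariate_log_rr(units, config)
    rr = np.exp(log_rr)
    years = np.asarray(config.years)
    mid_year = years.mean()
    trend = np.exp(config.annual_trend * (years - mid_year))
    pop = units["population"].to_numpy(float)

    # (unit, band, sex, year) expected counts via outer products
    band_share = np.array([shares[b] for b in AGE_BANDS])
    band_mult = np.array([mult[b] for b in AGE_BANDS])
    sex_split = np.full(2, 0.5)
    lam = (
        (pop * rr)[:, None, None, None]
        * (band_share * band_mult)[None, :, None, None]
        * sex_split[None, None, :, None]
        * (config.base_rate / 1e5)
        * trend[None, None, None, :]
    )
    idx = pd.MultiIndex.from_product(
        [units["unit_id"], AGE_BANDS, ["male", "female"], years],
        names=["unit_id", "age_band", "sex", "year"],
    )
    return pd.DataFrame({"expected": lam.ravel()}, index=idx).reset_index()


def _dates_from_curve(
    rng: np.random.Generator, years: np.ndarray, curve: np.ndarray
) -> pd.Series:
    doy = rng.choice(np.arange(1, DAYS_IN_YEAR + 1), size=len(years), p=curve / curve.sum())
    jan1 = pd.to_datetime(pd.Series(years).astype(int).astype(str) + "-01-01")
    return jan1 + pd.to_timedelta(doy - 1, unit="D")


def generate_deaths(
    units: pd.DataFrame, surface: TrueSurface, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate the death-record table observed by the survey.

    Snakebite deaths are Poisson with the unit/age/sex/year expectations of
    :func:`expected_snakebite_deaths`; dates follow the seasonal curve.  The
    first physician always codes a true snakebite death X20; the second
    agrees with probability ``coder_agreement`` and otherwise codes X27 or
    X29.  Non-snakebite deaths (``other_cause_ratio`` per expected snakebite
    death, allocated across units by population) carry unrelated ICD-10
    codes, optionally with spurious X27/X29 codes at ``confusion_rate``.
    """
    missing = set(units["unit_id"]) - set(surface.unit_ids)
    if missing:
        raise AlignmentError(f"units missing from true surface: {sorted(missing)[:5]}")
    rng = np.random.default_rng(config.seed + 2)
    expected = expected_snakebite_deaths(units, surface, config)
    counts = rng.poisson(expected["expected"].to_numpy())
    reps = np.repeat(expected.index.to_numpy(), counts)
    snake = expected.loc[reps, ["unit_id", "age_band", "sex", "year"]].reset_index(drop=True)
    n_snake = len(snake)

    lower = snake["age_band"].map(AGE_BAND_LOWER).to_numpy()
    width = np.where(lower >= 85, 15, 5)
    snake["age"] = lower + rng.integers(0, width)
    snake["date_of_death"] = _dates_from_curve(
        rng, snake["year"].to_numpy(), surface.seasonal
    )
    in_hosp = rng.random(n_snake) < config.hospital_fraction
    other_place = rng.random(n_snake) < 0.15
    snake["place"] = np.where(in_hosp, "hospital", np.where(other_place, "other", "home"))
    snake["coder1_icd10"] = "X20"
    agree = rng.random(n_snake) < config.coder_agreement
    alt = rng.choice(["X27", "X29"], size=n_snake)
    snake["coder2_icd10"] = np.where(agree, "X20", alt)
    snake["final_icd10"] = "X20"
    snake["true_cause"] = "snakebite"

    # interleaved non-snakebite deaths
    total_expected = expected["expected"].sum()
    n_other = rng.poisson(config.other_cause_ratio * total_expected)
    pop = units["population"].to_numpy(float)
    unit_idx = rng.choice(len(units), size=n_other, p=pop / pop.sum())
    shares = standard_population_weights()
    bands = rng.choice(AGE_BANDS, size=n_other, p=np.array([shares[b] for b in AGE_BANDS]))
    other = pd.DataFrame(
        {
            "unit_id": units["unit_id"].to_numpy()[unit_idx],
            "age_band": bands,
            "sex": rng.choice(["male", "female"], size=n_other),
            "year": rng.choice(np.asarray(config.years), size=n_other),
        }
    )
    lower_o = other["age_band"].map(AGE_BAND_LOWER).to_numpy()
    other["age"] = lower_o + rng.integers(0, np.where(lower_o >= 85, 15, 5))
    other["date_of_death"] = _dates_from_curve(
        rng, other["year"].to_numpy(), np.ones(DAYS_IN_YEAR)
    )
    other["place"] = rng.choice(["home", "hospital", "other"], size=n_other, p=[0.5, 0.4, 0.1])
    codes = rng.choice(OTHER_ICD10_CODES, size=n_other)
    other["coder1_icd10"] = codes
    other["coder2_icd10"] = codes
    confused = rng.random(n_other) < config.confusion_rate
    other.loc[confused, "coder2_icd10"] = rng.choice(["X27", "X29"], size=int(confused.sum()))
    other["final_icd10"] = codes
    other["true_cause"] = "other"

    deaths = pd.concat([snake, other], ignore_index=True)
    deaths = deaths.sample(frac=1.0, random_state=config.seed + 3).reset_index(drop=True)
    deaths.insert(0, "record_id", [f"R{i:07d}" for i in range(len(deaths))])
    meta = units.set_index("unit_id")
    deaths["rural"] = meta["rural"].loc[deaths["unit_id"]].to_numpy()
    deaths["sampling_weight"] = meta["sampling_weight"].loc[deaths["unit_id"]].to_numpy()
    return deaths


def review_results(deaths: pd.DataFrame) -> dict[str, bool]:
    """Review table for coder-disagreement candidates: the generator's true
    cause stands in for the study's symptom/keyword re-examination."""
    c1, c2 = deaths["coder1_icd10"], deaths["coder2_icd10"]
    snakeish = c1.isin(["X20", "X27", "X29"]) | c2.isin(["X20", "X27", "X29"])
    agreed = (c1 == "X20") & (c2 == "X20")
    cand = deaths.loc[snakeish & ~agreed]
    return dict(zip(cand["record_id"], cand["true_cause"] == "snakebite"))


def generate_literature_studies(
    n_studies: int,
    true_cfr: float,
    dispersion: float = 0.0,
    seed: int = 0,
    outlier_fraction: float = 0.0,
    outlier_cfr: float = 0.3,
    mean_bites: float = 600.0,
) -> pd.DataFrame:
    """Literature-review-style study table of bites and deaths.

    Per-study bite counts are heavy-tailed (log-normal); deaths are
    beta-binomial around ``true_cfr`` with overdispersion controlled by
    ``dispersion`` (0 = pure binomial).  A fraction of studies can be planted
    as outliers with an inflated case-fatality rate.
    """
    if n_studies < 3:
        raise ValueError("need at least 3 studies to characterise case fatality")
    if not 0 <= true_cfr < 1:
        raise ValueError("true_cfr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    bites = np.maximum(20, rng.lognormal(np.log(mean_bites), 1.0, n_studies)).astype(int)
    cfr = np.full(n_studies, float(true_cfr))
    n_out = int(round(outlier_fraction * n_studies))
    if n_out:
        cfr[rng.choice(n_studies, n_out, replace=False)] = outlier_cfr
    if dispersion > 0:
        k = 1.0 / dispersion
        p = np.array(
            [rng.beta(c * k, (1 - c) * k) if c > 0 else 0.0 for c in cfr]
        )
    else:
        p = cfr
    deaths = rng.binomial(bites, p)
    types = rng.choice(["hospital", "community"], size=n_studies, p=[0.9, 0.1])
    return pd.DataFrame(
        {
            "study_id": [f"S{i:03d}" for i in range(n_studies)],
            "study_type": types,
            "bites": bites,
            "deaths": deaths,
        }
    )


def envelope_from_truth(
    units: pd.DataFrame, surface: TrueSurface, config: SimulationConfig
) -> pd.DataFrame:
    """All-cause death envelope consistent with the generator.

    Expected all-cause deaths per year and age band (snakebite expectation
    plus the interleaved other-cause expectation, which is distributed over
    age by population share), with the person-years denominator.  Plays the
    role of the externally estimated demographic death totals.
    """
    expected = expected_snakebite_deaths(units, surface, config)
    snake = expected.groupby(["year", "age_band"], as_index=False)["expected"].sum()
    total_snake = expected["expected"].sum()
    shares = standard_population_weights()
    pop_total = units["population"].sum()
    rows = []
    for year in config.years:
        for band in AGE_BANDS:
            e_snake = float(
                snake.loc[(snake["year"] == year) & (snake["age_band"] == band), "expected"].sum()
            )
            e_other = config.other_cause_ratio * total_snake / config.n_years * shares[band]
            rows.append(
                {
                    "year": year,
                    "age_band": band,
                    "total_deaths": e_snake + e_other,
                    "population": pop_total * shares[band],
                }
            )
    return pd.DataFrame(rows)


def simulate(config: SimulationConfig) -> dict:
    """Run the full generator; returns units, populations, surface, deaths,
    review table, envelope and the scalar truth record."""
    units = generate_units(config)
    surface = generate_true_surface(units, config)
    deaths = generate_deaths(units, surface, config)
    studies = generate_literature_studies(78, true_cfr=0.032, dispersion=0.001,
                                          seed=config.seed + 5)
    truth = {
        "base_rate": config.base_rate,
        "seasonal_amplitude": config.seasonal_amplitude,
        "peak_day": config.peak_day,
        "monsoon_share": monsoon_share_of_curve(surface.seasonal),
        "coder_agreement": config.coder_agreement,
        "hospital_fraction": config.hospital_fraction,
        "annual_trend": config.annual_trend,
        "spatial_sd": config.spatial_sd,
        "spatial_range": config.spatial_range,
        "n_snakebite_deaths": int((deaths["true_cause"] == "snakebite").sum()),
    }
    return {
        "config": config,
        "units": units,
        "populations": age_sex_population(units),
        "surface": surface,
        "deaths": deaths,
        "review": review_results(deaths),
        "envelope": envelope_from_truth(units, surface, config),
        "studies": studies,
        "truth": truth,
    }


def write_outputs(outdir: str | Path, sim: dict) -> None:
    """Write units.csv, deaths.csv, envelope.csv, true_surface.csv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim["units"].to_csv(outdir / "units.csv", index=False)
    sim["deaths"].to_csv(outdir / "deaths.csv", index=False)
    sim["envelope"].to_csv(outdir / "envelope.csv", index=False)
    sim["studies"].to_csv(outdir / "studies.csv", index=False)
    sim["surface"].grid.to_csv(outdir / "true_surface.csv", name="log_rr")
    pd.Series(sim["review"], name="is_snakebite").rename_axis("record_id").to_csv(
        outdir / "review.csv"
    )
    (outdir / "truth.json").write_text(json.dumps(sim["truth"], indent=2))
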