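"""End-to-end assembly of the estimation chain.

Convenience drivers that connect the modules the way the full analysis runs:
classified deaths and unit demography feed the national age-sex rate model;
its expectations feed the geostatistical relative-risk model; the predicted
surface is scaled by the national risk before 70 into absolute risk, and
overlaid on a population grid for population-at-risk summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from snakeburden import rates, spatial, va_records
from snakeburden.config import BANDS_UNDER_70


def exposure_table(
    populations: pd.DataFrame, years: list[int] | tuple[int, ...]
) -> pd.DataFrame:
    """Person-years per (unit, age band, sex, year), ages 0-69.

    ``populations`` is long (unit_id, age_band, sex, population); each
    calendar year contributes the unit population as person-years.
    """
    pops = populations[populations["age_band"].isin(BANDS_UNDER_70)]
    frames = []
    for year in years:
        f = pops.copy()
        f["year"] = year
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    return out.rename(columns={"population": "person_years"})


def snakebite_death_counts(
    deaths: pd.DataFrame, review: dict | None = None
) -> pd.DataFrame:
    """Centrally classified snakebite deaths (ages 0-69) per
    unit x age band x sex x year."""
    cls = va_records.classify_records(deaths, review)
    mask = cls.isin([va_records.INCLUDED_AGREED, va_records.INCLUDED_AFTER_REVIEW])
    sb = deaths.loc[mask & deaths["age_band"].isin(BANDS_UNDER_70)]
    return sb.groupby(
        ["unit_id", "age_band", "sex", "year"], as_index=False, observed=True
    ).size().rename(columns={"size": "deaths"})


def make_grid_covariates(units: pd.DataFrame, cell: float = 1.0) -> pd.DataFrame:
    """Regular lon-lat grid over the units' bounding box with covariates
    taken from the nearest sampling unit (nearest-neighbour assignment)."""
    lon0, lon1 = units["lon"].min(), units["lon"].max()
    lat0, lat1 = units["lat"].min(), units["lat"].max()
    lons = np.arange(lon0, lon1 + cell, cell)
    lats = np.arange(lat0, lat1 + cell, cell)
    cols, rows = np.meshgrid(np.arange(len(lons)), np.arange(len(lats)))
    grid = pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "lon": lons[cols.ravel()],
            "lat": lats[rows.ravel()],
        }
    )
    tree = cKDTree(units[["lon", "lat"]].to_numpy())
    _, nearest = tree.query(grid[["lon", "lat"]].to_numpy())
    for c in ("rural", "altitude_m", "temperature_c", "female_illiteracy"):
        grid[c] = units[c].to_numpy()[nearest]
    grid["rural"] = grid["rural"].astype(float)
    grid["altitude_km"] = grid["altitude_m"] / 1000.0
    grid["rural_illiteracy"] = grid["rural"] * grid["female_illiteracy"]
    return grid


def make_population_grid(units: pd.DataFrame, grid: pd.DataFrame) -> pd.DataFrame:
    """Population raster on the same geometry: each unit's population is
    assigned to its nearest grid cell."""
    tree = cKDTree(grid[["lon", "lat"]].to_numpy())
    _, nearest = tree.query(units[["lon", "lat"]].to_numpy())
    pop = np.zeros(len(grid))
    np.add.at(pop, nearest, units["population"].to_numpy(float))
    out = grid[["row", "col", "lon", "lat"]].copy()
    out["population"] = pop
    return out


def national_risk_before_70(model: spatial.NationalRateModel) -> float:
    """Risk (%) of dying of the cause before 70 implied by the national
    age-sex rates (sexes averaged within band)."""
    band_rates = model.rates.groupby("age_band")["rate_per_100k"].mean()
    band_rates = band_rates.reindex(list(BANDS_UNDER_70)).fillna(0.0)
    return rates.risk_before_70(band_rates)


def run_spatial(
    units: pd.DataFrame,
    populations: pd.DataFrame,
    deaths: pd.DataFrame,
    years: list[int] | tuple[int, ...],
    review: dict | None = None,
    grid_cell: float = 1.0,
    thresholds: tuple[float, ...] = (0.6, 1.0),
    **fit_kwargs,
) -> dict:
    """Fit national rates, the geostatistical RR model, the predicted
    absolute-risk surface, and population-at-risk summaries."""
    exposure = exposure_table(populations, years)
    counts = snakebite_death_counts(deaths, review)
    cells = exposure.merge(counts, on=["unit_id", "age_band", "sex", "year"], how="left")
    cells["deaths"] = cells["deaths"].fillna(0.0)

    national = spatial.fit_national_rates(
        cells.groupby(["age_band", "sex", "year"], as_index=False).agg(
            deaths=("deaths", "sum"), person_years=("person_years", "sum")
        )
    )
    cells["expected"] = national.expected_deaths(cells)
    per_unit = cells.groupby("unit_id", as_index=False).agg(
        deaths=("deaths", "sum"), expected=("expected", "sum")
    )
    meta = units.set_index("unit_id")
    per_unit["lon"] = meta["lon"].loc[per_unit["unit_id"]].to_numpy()
    per_unit["lat"] = meta["lat"].loc[per_unit["unit_id"]].to_numpy()
    per_unit["rural"] = meta["rural"].loc[per_unit["unit_id"]].to_numpy(float)
    per_unit["altitude_km"] = meta["altitude_m"].loc[per_unit["unit_id"]].to_numpy() / 1000.0
    per_unit["temperature_c"] = meta["temperature_c"].loc[per_unit["unit_id"]].to_numpy()
    per_unit["rural_illiteracy"] = (
        per_unit["rural"] * meta["female_illiteracy"].loc[per_unit["unit_id"]].to_numpy()
    )

    geo = spatial.fit_geostatistical_rr(per_unit, **fit_kwargs)
    grid = make_grid_covariates(units, cell=grid_cell)
    surface = spatial.predict_rr_grid(geo, grid)
    risk70 = national_risk_before_70(national)
    abs_surface = spatial.absolute_risk(surface, risk70, thresholds=thresholds)
    pop_grid = make_population_grid(units, grid)
    par = spatial.population_at_risk(abs_surface, pop_grid, thresholds=thresholds)
    return {
        "national": national,
        "geo": geo,
        "unit_data": per_unit,
        "surface": abs_surface,
        "population_grid": pop_grid,
        "population_at_risk": par,
        "national_risk_before_70_pct": risk70,
    }
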