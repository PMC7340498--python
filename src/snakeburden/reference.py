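"""Bundled published summary tables for India's snakebite burden.

Small reference CSVs shipped with the package: the yearly national study
summary (study deaths, standardized and age-specific rates, risk before 70,
envelope-scaled national totals for 2001-2014), the spline-projected
national totals for 2000 and 2015-2019, the 20-year age-sex death totals
with coding-agreement bounds, state-level government hospital reports with
the corresponding survey-based hospital-death estimates, and a table of
published scalar constants (dual-coder counts, ambulance-cohort outcomes,
bite-range assumptions).  These let the arithmetic layers of the package be
exercised against published national numbers without access to the
restricted record-level survey data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_PKG = "snakeburden.data"


def _read(name: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath(name).open() as fh:
        return pd.read_csv(fh)


def yearly_summary() -> pd.DataFrame:
    """Per-year national summary, 2001-2014."""
    return _read("india_snakebite_by_year.csv")


def projected_totals() -> pd.DataFrame:
    """Spline-projected national death totals for 2000 and 2015-2019."""
    return _read("india_snakebite_projection.csv")


def age_sex_totals() -> pd.DataFrame:
    """20-year (2000-2019) death totals in thousands by age range and sex,
    with lower/upper coding-agreement bounds."""
    return _read("india_snakebite_by_age_sex.csv")


def hospital_reports() -> pd.DataFrame:
    """State-level government-reported bites/deaths (thousands, 2003-2015)
    alongside survey-based total and in-hospital death estimates."""
    return _read("india_hospital_reports.csv")


def constants() -> dict[str, float]:
    """Published scalar constants (dual-coder counts, ambulance cohort,
    national bite-range bounds)."""
    df = _read("india_published_constants.csv")
    return dict(zip(df["name"], df["value"]))
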