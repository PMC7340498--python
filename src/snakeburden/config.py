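"""Simulation configuration and shared demographic constants.

Age is handled internally in 5-year bands 0-4 ... 85+ (18 bands); the broad
groups used in summary tables (0-14, 15-29, 30-69, 70+) are presentation
aggregations.  The bundled standard population is an India-2001-census-like
age pyramid used for age standardization; cumulative-risk-before-70
calculations use the 14 bands from 0-4 to 65-69.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

AGE_BANDS: tuple[str, ...] = tuple(
    [f"{lo}-{lo + 4}" for lo in range(0, 85, 5)] + ["85+"]
)
AGE_BAND_LOWER: dict[str, int] = {b: 5 * i for i, b in enumerate(AGE_BANDS)}
BANDS_UNDER_70: tuple[str, ...] = AGE_BANDS[:14]

#: India-2001-like standard population: share of the population per 5-year
#: band, a young pyramid with steadily declining older bands.  Used as the
#: default standard for age standardization and as the default age structure
#: of simulated sampling-unit populations.
STANDARD_POPULATION_SHARES: dict[str, float] = {
    "0-4": 0.1075,
    "5-9": 0.1152,
    "10-14": 0.1122,
    "15-19": 0.0975,
    "20-24": 0.0887,
    "25-29": 0.0829,
    "30-34": 0.0744,
    "35-39": 0.0702,
    "40-44": 0.0591,
    "45-49": 0.0505,
    "50-54": 0.0411,
    "55-59": 0.0314,
    "60-64": 0.0288,
    "65-69": 0.0208,
    "70-74": 0.0159,
    "75-79": 0.0088,
    "80-84": 0.0055,
    "85+": 0.0045,
}

#: Relative age pattern of snakebite mortality: children and middle-aged
#: adults (field work, outdoor exposure) at moderately high risk, young
#: adults lower, a mild rise at older ages.  Normalized at config time so the
#: age-standardized rate under the bundled standard equals ``base_rate``.
_RAW_AGE_PATTERN: dict[str, float] = {
    **{b: 0.94 for b in AGE_BANDS[0:3]},   # 0-14
    **{b: 0.65 for b in AGE_BANDS[3:6]},   # 15-29
    **{b: 1.21 for b in AGE_BANDS[6:14]},  # 30-69
    **{b: 1.20 for b in AGE_BANDS[14:]},   # 70+
}

#: ICD-10 codes used for the interleaved non-snakebite deaths.  Only their
#: count matters downstream; the list is a fixed mix of common causes.
OTHER_ICD10_CODES: tuple[str, ...] = (
    "I21", "I64", "J18", "J44", "A09", "C34", "E11", "V89", "W74", "X09",
)


class ConfigurationError(ValueError):
    """An invalid simulation configuration field, named in the message."""


def _check(condition: bool, fieldname: str, message: str) -> None:
    if not condition:
        raise ConfigurationError(f"{fieldname}: {message}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey generator.

    The defaults describe the study conditions being emulated: ~7,400
    geocoded sampling units in rural/urban strata with 94% of the population
    rural, a base snakebite mortality of 4.8 deaths per 100,000 person-years,
    monsoon-peaked seasonality with a mid-July peak, 92% immediate dual-coder
    agreement and 23% of deaths occurring in hospital.

    Parameters
    ----------
    n_units
        Number of sampling units (>= 2).
    seed
        Seed for the generator; identical config + seed gives identical output.
    base_rate
        Age-standardized snakebite death rate, per 100,000 person-years.
    spatial_range
        Correlation length (degrees) of the Matern spatial log-RR field.
    spatial_sd
        Standard deviation of the spatial log relative risk (0 disables it).
    seasonal_amplitude
        Amplitude A of the log-scale annual sinusoid
        ``exp(A * cos(2*pi*(day - peak_day)/365))``; 0 gives a flat year.
        The peak-to-trough ratio is ``exp(2 A)``.
    peak_day
        Day of year of the seasonal peak (default 196, mid-July).
    coder_agreement
        Probability that the second physician also codes a true snakebite
        death to X20 (the first always does).
    hospital_fraction
        Probability a death occurs in hospital.
    covariate_effects
        Map covariate name -> log-RR per unit of the covariate; recognised
        names are ``rural`` (flag), ``altitude_km``, ``temperature_c`` and
        ``female_illiteracy`` (fraction).  Covariates are centred at their
        population-weighted means so the national base rate is unaffected.
    rural_share
        Target share of the population living in rural units.
    years
        Calendar years covered by the simulated survey.
    mean_unit_population
        Mean sampling-unit population (log-normal across units).
    other_cause_ratio
        Expected non-snakebite deaths per expected snakebite death.
    annual_trend
        Log-linear annual trend in the snakebite rate (e.g. -0.008 for a
        0.8%/year decline), centred on the middle study year.
    rural_weight, urban_weight
        SRS-style probability-of-selection sampling weights by stratum.
    confusion_rate
        Probability that a non-snakebite death receives a spurious X27/X29
        code from one coder (review resolves these as not snakebite).
    """

    n_units: int = 7377
    seed: int = 0
    base_rate: float = 4.8
    spatial_range: float = 2.0
    spatial_sd: float = 0.5
    seasonal_amplitude: float = 0.66
    peak_day: int = 196
    coder_agreement: float = 0.92
    hospital_fraction: float = 0.23
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    rural_share: float = 0.94
    years: tuple[int, ...] = tuple(range(2001, 2015))
    mean_unit_population: float = 3000.0
    other_cause_ratio: float = 9.0
    annual_trend: float = 0.0
    rural_weight: float = 1.0
    urban_weight: float = 1.0
    confusion_rate: float = 0.0
    lon_range: tuple[float, float] = (68.0, 90.0)
    lat_range: tuple[float, float] = (8.0, 32.0)

    def __post_init__(self) -> None:
        _check(self.n_units >= 2, "n_units", "need at least 2 sampling units")
        _check(self.base_rate > 0, "base_rate", "must be positive")
        _check(self.spatial_range > 0, "spatial_range", "must be positive")
        _check(self.spatial_sd >= 0, "spatial_sd", "must be non-negative")
        _check(self.seasonal_amplitude >= 0, "seasonal_amplitude", "must be >= 0")
        _check(0 <= self.coder_agreement <= 1, "coder_agreement", "must be in [0, 1]")
        _check(0 <= self.hospital_fraction <= 1, "hospital_fraction", "must be in [0, 1]")
        _check(0 <= self.rural_share <= 1, "rural_share", "must be in [0, 1]")
        _check(0 <= self.confusion_rate <= 1, "confusion_rate", "must be in [0, 1]")
        _check(self.mean_unit_population > 0, "mean_unit_population", "must be positive")
        _check(self.other_cause_ratio >= 0, "other_cause_ratio", "must be >= 0")
        _check(self.rural_weight > 0, "rural_weight", "must be positive")
        _check(self.urban_weight > 0, "urban_weight", "must be positive")
        _check(len(self.years) >= 1, "years", "need at least one year")
        unknown = set(self.covariate_effects) - {
            "rural", "altitude_km", "temperature_c", "female_illiteracy"
        }
        _check(not unknown, "covariate_effects", f"unknown covariates {sorted(unknown)}")

    @property
    def n_years(self) -> int:
        return len(self.years)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def standard_population_weights() -> dict[str, float]:
    """The bundled standard population shares (sum to 1)."""
    total = sum(STANDARD_POPULATION_SHARES.values())
    return {b: v / total for b, v in STANDARD_POPULATION_SHARES.items()}


def age_rate_multipliers() -> dict[str, float]:
    """Per-band rate multipliers m_a with sum_a w_a m_a = 1 under the
    bundled standard, so the standardized rate equals ``base_rate``."""
    w = standard_population_weights()
    norm = sum(w[b] * _RAW_AGE_PATTERN[b] for b in AGE_BANDS)
    return {b: _RAW_AGE_PATTERN[b] / norm for b in AGE_BANDS}


def broad_band(age_band: str) -> str:
    """Map a 5-year band to the presentation groups 0-14/15-29/30-69/70+."""
    lo = AGE_BAND_LOWER[age_band]
    if lo < 15:
        return "0-14"
    if lo < 30:
        return "15-29"
    if lo < 70:
        return "30-69"
    return "70+"
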