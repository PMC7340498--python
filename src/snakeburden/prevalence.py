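"""Indirect prevalence estimation from case fatality.

A literature-review table of per-study bites and deaths yields a pooled
in-hospital case-fatality rate (CFR) by ordinary least squares of deaths on
bites through the origin (a study with no bites implies no deaths), with a
single-pass standardized-residual outlier cut.  National bite totals are then
back-calculated: estimated in-hospital deaths divided by the CFR give
in-hospital bites, a scenario-specific out-of-hospital:in-hospital ratio
scales up to total bites, and a fixed envenomation share splits totals into
envenomations and dry/non-venomous bites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class EstimationError(ValueError):
    pass


@dataclass
class CfrEstimate:
    """Pooled case-fatality rate from a through-origin regression."""

    cfr: float
    se: float
    ci: tuple[float, float]
    n_used: int
    excluded: list[str]
    intercept: float | None = None


def estimate_cfr(
    studies: pd.DataFrame,
    outlier_threshold: float = 3.0,
    through_origin: bool = True,
    study_types: tuple[str, ...] = ("hospital", "community", "EMS"),
) -> CfrEstimate:
    """Estimate the case-fatality rate from study bite/death pairs.

    Restricted to study types reporting both bites and deaths; the slope of
    deaths on bites (through the origin by default) is the CFR.  Studies
    whose standardized residual exceeds ``outlier_threshold`` in absolute
    value are removed once, and the regression refitted.  Residuals are
    standardized by a size-dependent scale (variance proportional to bites,
    as for count outcomes), so large studies are not over-flagged merely for
    having large absolute residuals.
    """
    df = studies[
        studies["study_type"].isin(study_types)
        & studies["bites"].notna()
        & studies["deaths"].notna()
        & (studies["bites"] > 0)
    ].copy()
    if len(df) < 3:
        raise EstimationError(f"only {len(df)} usable studies; need at least 3")

    def fit(d: pd.DataFrame) -> tuple[float, float, float | None, np.ndarray]:
        x = d["bites"].to_numpy(float)
        y = d["deaths"].to_numpy(float)
        if through_origin:
            slope = float((x @ y) / (x @ x))
            resid = y - slope * x
            dof = max(len(d) - 1, 1)
            mse = float(resid @ resid) / dof
            se = float(np.sqrt(mse / (x @ x)))
            return slope, se, None, resid
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = max(len(d) - 2, 1)
        mse = float(resid @ resid) / dof
        cov = mse * np.linalg.inv(X.T @ X)
        return float(coef[1]), float(np.sqrt(cov[1, 1])), float(coef[0]), resid

    slope, se, intercept, resid = fit(df)
    x = df["bites"].to_numpy(float)
    scaled = resid / np.sqrt(x)
    s = scaled.std(ddof=1) if len(scaled) > 1 else 0.0
    if s > 0:
        keep = np.abs(scaled / s) <= outlier_threshold
    else:
        keep = np.ones(len(df), bool)
    excluded = df.loc[~keep, "study_id"].tolist()
    df_kept = df.loc[keep]
    if len(df_kept) < 3:
        raise EstimationError("outlier removal left fewer than 3 studies")
    if excluded:
        slope, se, intercept, _ = fit(df_kept)
    return CfrEstimate(
        cfr=slope,
        se=se,
        ci=(slope - 1.96 * se, slope + 1.96 * se),
        n_used=len(df_kept),
        excluded=excluded,
        intercept=intercept,
    )


def inhospital_prevalence(hospital_deaths: float, cfr: float) -> float:
    """In-hospital bites = hospital deaths / case-fatality rate."""
    if cfr <= 0:
        raise ZeroDivisionError("case-fatality rate must be positive")
    return hospital_deaths / cfr


def total_bites(scenarios: pd.DataFrame) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Per-scenario national bite totals and their min-max range.

    ``scenarios`` has one row per assumption set with columns
    ``hospital_deaths``, ``cfr`` and ``out_to_in_ratio`` (out-of-hospital
    bites per in-hospital bite); optional ``scenario`` labels and
    ``envenomation_share`` are echoed through for audit.
    """
    if len(scenarios) == 0:
        raise EstimationError("no scenarios provided")
    out = scenarios.copy()
    out["in_hospital_bites"] = [
        inhospital_prevalence(d, c) for d, c in zip(out["hospital_deaths"], out["cfr"])
    ]
    if (out["out_to_in_ratio"] < 0).any():
        raise EstimationError("out_to_in_ratio must be non-negative")
    out["total_bites"] = out["in_hospital_bites"] * (1.0 + out["out_to_in_ratio"])
    rng = (float(out["total_bites"].min()), float(out["total_bites"].max()))
    return out, rng


def partition_envenomation(
    total: float, envenomation_share: float = 0.70
) -> tuple[float, float]:
    """Split total bites into (envenomations, dry/non-venomous bites)."""
    if not 0 <= envenomation_share <= 1:
        raise EstimationError("envenomation_share must be in [0, 1]")
    env = total * envenomation_share
    return env, total - env


def burden_summary(
    scenarios: pd.DataFrame, envenomation_share: float = 0.70
) -> dict:
    """Report-mode summary: bite and envenomation ranges in millions (2 dp)."""
    table, (lo, hi) = total_bites(scenarios)
    env_lo, dry_lo = partition_envenomation(lo, envenomation_share)
    env_hi, dry_hi = partition_envenomation(hi, envenomation_share)
    return {
        "total_bites_million": (round(lo / 1e6, 2), round(hi / 1e6, 2)),
        "envenomations_million": (round(env_lo / 1e6, 2), round(env_hi / 1e6, 2)),
        "dry_bites_million": (round(dry_lo / 1e6, 2), round(dry_hi / 1e6, 2)),
        "scenarios": table,
    }
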