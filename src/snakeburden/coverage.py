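"""Surveillance-coverage arithmetic.

Compares officially reported hospital snakebite deaths against
model-estimated in-hospital deaths, region by region: estimated hospital
deaths are total estimated deaths times the in-hospital fraction, and
coverage is reported deaths over estimated hospital deaths.  The national
aggregate uses summed numerators and denominators, never averaged
percentages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class ReconciliationError(ValueError):
    pass


def coverage_table(
    reported: pd.DataFrame,
    estimated: pd.DataFrame,
    rounding: str = "raw",
    national_label: str = "National",
) -> pd.DataFrame:
    """Per-region and aggregate surveillance coverage.

    Parameters
    ----------
    reported
        Columns ``region``, ``reported_bites`` and ``reported_deaths``
        (thousands, as published).
    estimated
        Columns ``region`` plus either ``est_total_deaths`` and
        ``in_hospital_fraction`` or a precomputed ``est_hospital_deaths``.
    rounding
        ``"raw"`` keeps full precision; ``"table"`` rounds counts to one
        decimal (thousands) and coverage to integer percent, matching
        publication style.  Printed tables typically round cells computed
        from unrounded intermediates, so comparisons against published
        numbers should use raw mode with one-unit-in-the-last-digit slack.
    """
    if rounding not in {"raw", "table"}:
        raise ValueError("rounding must be 'raw' or 'table'")
    only_reported = set(reported["region"]) - set(estimated["region"])
    only_estimated = set(estimated["region"]) - set(reported["region"])
    if only_reported or only_estimated:
        raise ReconciliationError(
            f"regions only in reported: {sorted(only_reported)}; "
            f"only in estimated: {sorted(only_estimated)}"
        )
    merged = reported.merge(estimated, on="region", validate="one_to_one")
    if "est_hospital_deaths" not in merged.columns:
        merged["est_hospital_deaths"] = (
            merged["est_total_deaths"] * merged["in_hospital_fraction"]
        )
    merged["coverage_pct"] = np.where(
        merged["est_hospital_deaths"] > 0,
        merged["reported_deaths"] / merged["est_hospital_deaths"] * 100.0,
        np.nan,
    )
    nat = {
        "region": national_label,
        "reported_bites": merged["reported_bites"].sum(),
        "reported_deaths": merged["reported_deaths"].sum(),
        "est_hospital_deaths": merged["est_hospital_deaths"].sum(),
    }
    if "est_total_deaths" in merged.columns:
        nat["est_total_deaths"] = merged["est_total_deaths"].sum()
        nat["in_hospital_fraction"] = (
            nat["est_hospital_deaths"] / nat["est_total_deaths"]
            if nat["est_total_deaths"] > 0
            else np.nan
        )
    nat["coverage_pct"] = (
        nat["reported_deaths"] / nat["est_hospital_deaths"] * 100.0
        if nat["est_hospital_deaths"] > 0
        else np.nan
    )
    out = pd.concat([merged, pd.DataFrame([nat])], ignore_index=True)
    if rounding == "table":
        for c in ("reported_bites", "reported_deaths", "est_total_deaths",
                  "est_hospital_deaths"):
            if c in out.columns:
                out[c] = out[c].round(1)
        out["coverage_pct"] = out["coverage_pct"].round(0)
    return out
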