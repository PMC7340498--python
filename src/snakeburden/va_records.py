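"""Dual-coder classification of verbal-autopsy snakebite deaths.

Each death record carries independent ICD-10 assignments from two
physicians.  A record is a confirmed snakebite when both coded X20 (contact
with venomous snakes).  Records where at least one coder used X20, X27
(other venomous animals) or X29 (unspecified venomous animal or plant) but
the pair did not agree on X20 are *candidates*, resolved by an explicit
review table (in synthetic pipelines, the generator's true cause).  The
dual-coding pattern also yields plausible lower/central/upper counts: the
lower bound requires immediate agreement, the upper bound admits any record
with a single X20 code (plus review-eligible X27/X29 pairs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

SNAKEBITE_CODE = "X20"
CANDIDATE_CODES = frozenset({"X20", "X27", "X29"})

INCLUDED_AGREED = "included_agreed"
INCLUDED_AFTER_REVIEW = "included_after_review"
EXCLUDED = "excluded"

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9]?$")


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class CodedCounts:
    """Snakebite death counts under the three coding-agreement rules."""

    lower: int
    central: int
    upper: int
    immediate_agreement_fraction: float

    def __post_init__(self) -> None:
        if not self.lower <= self.central <= self.upper:
            raise ValidationError(
                f"bounds not ordered: {self.lower} <= {self.central} <= {self.upper}"
            )


def _validate_code(code: str, record_id: str | None = None) -> str:
    code = str(code).strip().upper()
    if not _ICD10_RE.match(code):
        where = f" (record {record_id})" if record_id else ""
        raise ValidationError(f"malformed ICD-10 code {code!r}{where}")
    return code


def classify_record(
    coder1: str,
    coder2: str,
    review: bool | None = None,
    record_id: str | None = None,
) -> str:
    """Classify one record from its two codes and an optional review flag.

    Pure function: both X20 -> included_agreed; any other pattern touching
    {X20, X27, X29} -> included_after_review when the review flag is true,
    otherwise excluded (a candidate without review is not counted); no
    snakebite-related code -> excluded.
    """
    c1 = _validate_code(coder1, record_id)
    c2 = _validate_code(coder2, record_id)
    if c1 == SNAKEBITE_CODE and c2 == SNAKEBITE_CODE:
        return INCLUDED_AGREED
    if c1 in CANDIDATE_CODES or c2 in CANDIDATE_CODES:
        return INCLUDED_AFTER_REVIEW if review else EXCLUDED
    return EXCLUDED


def classify_records(
    records: pd.DataFrame, review_results: Mapping[str, bool] | None = None
) -> pd.Series:
    """Vectorised :func:`classify_record` over a death-record table."""
    review_results = review_results or {}
    out = []
    for rid, c1, c2 in zip(
        records["record_id"], records["coder1_icd10"], records["coder2_icd10"]
    ):
        out.append(classify_record(c1, c2, review_results.get(rid), rid))
    return pd.Series(out, index=records.index, name="classification")


def coding_bounds(
    records: pd.DataFrame,
    review_results: Mapping[str, bool] | None = None,
    include_x29_alone: bool = False,
) -> CodedCounts:
    """Lower/central/upper snakebite counts from the dual-coding pattern.

    lower
        Both coders X20 (immediate agreement).
    central
        lower plus candidates confirmed by review.
    upper
        lower plus every candidate with at least one X20 code, plus
        X27/X29-only candidates confirmed by review.  With
        ``include_x29_alone`` every candidate enters the upper bound (the
        reading in which a lone X27/X29 already counts as a snakebite code).

    The immediate-agreement fraction is lower / (lower + all candidates),
    i.e. the share of probable snakebite deaths on which the physicians
    agreed without review.
    """
    if len(records) == 0:
        return CodedCounts(0, 0, 0, 0.0)
    review_results = review_results or {}
    c1 = records["coder1_icd10"].astype(str).str.strip().str.upper()
    c2 = records["coder2_icd10"].astype(str).str.strip().str.upper()
    bad = ~(c1.str.match(_ICD10_RE) & c2.str.match(_ICD10_RE))
    if bad.any():
        rid = records.loc[bad, "record_id"].iloc[0]
        raise ValidationError(f"malformed ICD-10 code (record {rid})")
    agreed = (c1 == SNAKEBITE_CODE) & (c2 == SNAKEBITE_CODE)
    touching = c1.isin(CANDIDATE_CODES) | c2.isin(CANDIDATE_CODES)
    candidate = touching & ~agreed
    confirmed = records["record_id"].map(lambda r: bool(review_results.get(r, False)))
    has_x20 = (c1 == SNAKEBITE_CODE) | (c2 == SNAKEBITE_CODE)

    lower = int(agreed.sum())
    central = lower + int((candidate & confirmed).sum())
    if include_x29_alone:
        upper = lower + int(candidate.sum())
    else:
        upper = lower + int((candidate & (has_x20 | confirmed)).sum())
    n_candidates = int(candidate.sum())
    frac = lower / (lower + n_candidates) if (lower + n_candidates) else 0.0
    return CodedCounts(lower, max(central, lower), max(upper, central, lower), frac)
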