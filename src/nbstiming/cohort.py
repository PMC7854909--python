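"""Newborn record model, cohort restriction rules, and age-at-collection binning.

A cohort is a :class:`pandas.DataFrame` with one row per infant.  Required
columns are listed in :data:`RECORD_COLUMNS`; every additional column is
treated as a metabolite concentration.  Age at blood collection (AaBC) is
stored as integer hours after birth; fractional hours are floored on ingest.

Two binning systems are used throughout the analysis:

* ten fine 6-hour windows covering 12-72 h (the last window is 66-72 h),
  with the first window (12-17 h) serving as the reference;
* three coarse collection categories: early (12-23 h), standard (24-48 h,
  the recommended collection window) and late (49-168 h), with the standard
  window serving as the reference.

All interval endpoints are inclusive on integer hours/grams/weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RECORD_COLUMNS",
    "RACE_VALUES",
    "CATEGORIES",
    "FINE_BINS",
    "AaBCScheme",
    "CohortFilterSpec",
    "apply_exclusions",
    "restrict_reference",
    "classify_race_ethnicity",
    "classify_race_ethnicity_frame",
    "assign_fine_bin",
    "assign_fine_bins",
    "assign_category",
    "assign_categories",
]

#: Required non-metabolite columns of a cohort table.
RECORD_COLUMNS = ["id", "aabc", "ga", "bw", "sex", "race_reported", "tpn", "screen"]

#: Race/ethnicity values that may appear in a reported set.
RACE_VALUES = frozenset({"Asian", "Black", "Hispanic", "White", "other"})

#: Coarse collection categories, inclusive hour ranges.
CATEGORIES = {"early": (12, 23), "standard": (24, 48), "late": (49, 168)}

#: Fine 6-hour windows (the last one spans 7 hours), inclusive hour ranges.
FINE_BINS = [
    (12, 17), (18, 23), (24, 29), (30, 35), (36, 41),
    (42, 47), (48, 53), (54, 59), (60, 65), (66, 72),
]


@dataclass(frozen=True)
class AaBCScheme:
    """The two AaBC binning systems and their reference groups."""

    fine_bins: tuple = tuple(FINE_BINS)
    categories: Mapping[str, tuple] = field(
        default_factory=lambda: dict(CATEGORIES)
    )
    reference_fine: int = 0
    reference_category: str = "standard"

    def __post_init__(self) -> None:
        hours = [h for lo, hi in self.fine_bins for h in range(lo, hi + 1)]
        if sorted(hours) != list(range(self.fine_bins[0][0], self.fine_bins[-1][1] + 1)):
            raise ValueError("fine bins must be disjoint and contiguous")
        cat_hours = [
            h for lo, hi in self.categories.values() for h in range(lo, hi + 1)
        ]
        if len(cat_hours) != len(set(cat_hours)):
            raise ValueError("categories must be disjoint")
        if self.reference_category not in self.categories:
            raise ValueError(f"unknown reference category {self.reference_category!r}")

    @property
    def category_names(self) -> list:
        return list(self.categories)

    @property
    def fine_labels(self) -> list:
        return [f"{lo}-{hi}" for lo, hi in self.fine_bins]


@dataclass(frozen=True)
class CohortFilterSpec:
    """Exclusion and reference-restriction rules for a screening cohort.

    ``aabc_range``, ``bw_range`` and ``ga_range`` are hard exclusion windows
    (a record outside any of them is removed); ``reference_ga`` and
    ``reference_bw`` define the term/normal-birth-weight reference subset used
    for the AaBC comparisons, which additionally requires TPN status "no".
    """

    aabc_range: tuple = (12, 168)
    bw_range: tuple = (1000, 5000)
    ga_range: tuple = (28, 42)
    reference_ga: tuple = (37, 41)
    reference_bw: tuple = (2500, 4000)
    drop_tpn: bool = True

    def __post_init__(self) -> None:
        for name in ("aabc_range", "bw_range", "ga_range", "reference_ga", "reference_bw"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper bound {hi}")


def _in_range(values: pd.Series, bounds: tuple) -> pd.Series:
    lo, hi = bounds
    return values.ge(lo) & values.le(hi)


def apply_exclusions(
    records: pd.DataFrame, spec: CohortFilterSpec | None = None
) -> tuple[pd.DataFrame, dict]:
    """Drop records violating the cohort exclusion rules.

    A record is removed iff it violates any rule; the returned tally
    attributes each dropped record to the *first* rule it violates, in the
    fixed order ``aabc -> bw -> ga -> tpn``, so counts are reproducible.
    Unknown (missing) AaBC drops under the aabc rule; TPN "yes" or "unknown"
    drops under the tpn rule when ``drop_tpn`` is enabled.

    Returns
    -------
    (retained, tally)
        The retained records (copy) and a dict rule-name -> dropped count.
    """
    spec = spec or CohortFilterSpec()
    aabc = pd.to_numeric(records["aabc"], errors="coerce")
    bad = {
        "aabc": aabc.isna() | ~_in_range(aabc, spec.aabc_range),
        "bw": ~_in_range(records["bw"], spec.bw_range),
        "ga": ~_in_range(records["ga"], spec.ga_range),
    }
    if spec.drop_tpn:
        bad["tpn"] = records["tpn"].isin(["yes", "unknown"]) | records["tpn"].isna()
    else:
        bad["tpn"] = pd.Series(False, index=records.index)

    tally = {}
    dropped_so_far = pd.Series(False, index=records.index)
    for rule in ("aabc", "bw", "ga", "tpn"):
        newly = bad[rule] & ~dropped_so_far
        tally[rule] = int(newly.sum())
        dropped_so_far |= bad[rule]
    return records.loc[~dropped_so_far].copy(), tally


def restrict_reference(
    records: pd.DataFrame, spec: CohortFilterSpec | None = None
) -> pd.DataFrame:
    """Keep only the reference subset: term GA, normal BW, TPN status "no".

    Expects :func:`apply_exclusions` to have been applied already; the
    operation is idempotent.
    """
    spec = spec or CohortFilterSpec()
    keep = (
        _in_range(records["ga"], spec.reference_ga)
        & _in_range(records["bw"], spec.reference_bw)
        & records["tpn"].eq("no")
    )
    return records.loc[keep].copy()


def classify_race_ethnicity(reported: Iterable[str] | str | None) -> str:
    """Collapse a reported race/ethnicity set to a single analysis category.

    Screening-program guideline cascade: (a) Hispanic if Hispanic is reported
    with anything else; (b) Black if Black is reported without Hispanic;
    (c) Asian if Asian is reported without Hispanic or Black; (d) White only
    if White is the sole reported value.  Everything else (including an empty
    or unknown report) is Other/Unknown.  Order-insensitive in its input.
    """
    if reported is None:
        return "Other/Unknown"
    if isinstance(reported, str):
        reported = [t for t in reported.split("|") if t]
    s = set(reported)
    unknown = s - RACE_VALUES
    if unknown:
        raise ValueError(f"unknown race/ethnicity value(s): {sorted(unknown)}")
    if "Hispanic" in s:
        return "Hispanic"
    if "Black" in s:
        return "Black"
    if "Asian" in s:
        return "Asian"
    if s == {"White"}:
        return "White"
    return "Other/Unknown"


def classify_race_ethnicity_frame(records: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_race_ethnicity` over the ``race_reported`` column."""
    return records["race_reported"].map(
        lambda v: classify_race_ethnicity(v if isinstance(v, (str, set, frozenset, list, tuple)) else None)
    )


def assign_fine_bin(aabc: float, scheme: AaBCScheme | None = None) -> int | None:
    """Index of the fine 6-h window containing ``aabc``; None outside 12-72 h."""
    scheme = scheme or AaBCScheme()
    for i, (lo, hi) in enumerate(scheme.fine_bins):
        if lo <= aabc <= hi:
            return i
    return None


def assign_category(aabc: float, scheme: AaBCScheme | None = None) -> str | None:
    """Collection category containing ``aabc``; None outside 12-168 h."""
    scheme = scheme or AaBCScheme()
    for name, (lo, hi) in scheme.categories.items():
        if lo <= aabc <= hi:
            return name
    return None


def assign_fine_bins(aabc: np.ndarray | pd.Series, scheme: AaBCScheme | None = None) -> pd.Series:
    """Vectorised fine-bin assignment; missing assignment is <NA>."""
    scheme = scheme or AaBCScheme()
    a = pd.Series(np.asarray(aabc), dtype="float64")
    out = pd.Series(pd.NA, index=a.index, dtype="Int64")
    for i, (lo, hi) in enumerate(scheme.fine_bins):
        out[a.between(lo, hi)] = i
    return out


def assign_categories(aabc: np.ndarray | pd.Series, scheme: AaBCScheme | None = None) -> pd.Series:
    """Vectorised category assignment; missing assignment is <NA>."""
    scheme = scheme or AaBCScheme()
    a = pd.Series(np.asarray(aabc), dtype="float64")
    out = pd.Series(pd.NA, index=a.index, dtype="object")
    for name, (lo, hi) in scheme.categories.items():
        out[a.between(lo, hi)] = name
    return out
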