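"""Observed-vs-expected false positives per collection window.

For each metabolic disorder the false-positive (FP) cases are tallied into
the early / standard / late collection windows and compared with the counts
expected if FP risk were independent of collection timing — i.e. expected
counts proportional to the screen-negative population shares of the windows.
A chi-squared goodness-of-fit test (df = 2) checks the overall distribution
and a per-window one-sample proportion test (df = 1) localises the excess or
deficit.  Each flagged disease-marker/window pair then receives a
consistency call: does the physiological marker shift in that window (the
screen-negative Cohen's d, oriented by whether the disease is detected
through an elevated or decreased marker) predict the observed FP excess or
deficit?

A transcription of the published per-disease FP counts, marker directions,
effect sizes and screen-negative window sizes ships with the package so the
whole table can be recomputed without any simulation
(:func:`load_published_fp_counts`, :func:`load_published_neg_sizes`).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AaBCScheme, CohortFilterSpec, assign_categories, restrict_reference

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseMarkerSpec",
    "FPCountTable",
    "EnrichmentResult",
    "ConsistencyCall",
    "load_published_fp_counts",
    "load_published_neg_sizes",
    "count_fp",
    "expected_counts",
    "gof_test",
    "category_test",
    "enrichment",
    "classify_consistency",
    "significance_stars",
    "table_report",
    "share_pct",
]

_CATS = ("early", "standard", "late")


@dataclass(frozen=True)
class DiseaseMarkerSpec:
    """A screened disorder, its primary marker and pathological direction."""

    disease: str
    marker: str
    direction: str  # "elevated" | "decreased"

    def __post_init__(self) -> None:
        if self.direction not in ("elevated", "decreased"):
            raise ValueError(f"direction must be elevated/decreased, got {self.direction!r}")


@dataclass(frozen=True)
class FPCountTable:
    """Observed FP counts per disease and collection window.

    ``counts`` is indexed by disease with columns early/standard/late;
    ``neg_sizes`` are the screen-negative window sizes that define the
    no-timing-effect expectation.
    """

    counts: pd.DataFrame
    neg_sizes: tuple

    def __post_init__(self) -> None:
        if (self.counts[list(_CATS)] < 0).any().any():
            raise ValueError("negative FP counts")
        if any(n <= 0 for n in self.neg_sizes):
            raise ValueError("screen-negative window sizes must be positive")

    @property
    def totals(self) -> pd.Series:
        return self.counts[list(_CATS)].sum(axis=1)

    def percentages(self) -> pd.DataFrame:
        """Window percentages of each disease's total, one decimal.

        Diseases with zero total get NaN (rendered as em-dash in reports).
        """
        tot = self.totals
        pct = self.counts[list(_CATS)].div(tot, axis=0) * 100.0
        pct[tot == 0] = np.nan
        return pct.round(1)


def load_published_fp_counts() -> pd.DataFrame:
    """Published per-disease FP counts, marker specs and effect sizes."""
    with resources.files("nbstiming.data").joinpath("published_fp_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="disease")


def load_published_neg_sizes() -> tuple:
    """Published screen-negative window sizes (early, standard, late)."""
    with resources.files("nbstiming.data").joinpath("screen_negative_sizes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="category")
    return tuple(int(df.loc[c, "n"]) for c in _CATS)


def published_count_table() -> FPCountTable:
    """The published FP counts as an :class:`FPCountTable`."""
    df = load_published_fp_counts()
    counts = df[["fp_early", "fp_standard", "fp_late"]].copy()
    counts.columns = list(_CATS)
    return FPCountTable(counts=counts, neg_sizes=load_published_neg_sizes())


def count_fp(
    fp_cases: pd.DataFrame,
    scheme: AaBCScheme | None = None,
    filters: CohortFilterSpec | None = None,
    neg_sizes: tuple | None = None,
) -> FPCountTable:
    """Tally FP cases per disease and collection window.

    The same reference restriction used for the screen-negatives (term GA,
    normal BW, no TPN) is applied first when those columns are present.
    Cases with AaBC outside 12-168 h are excluded and logged.
    """
    scheme = scheme or AaBCScheme()
    cases = fp_cases
    if filters is not None or {"ga", "bw", "tpn"}.issubset(cases.columns):
        cases = restrict_reference(cases, filters or CohortFilterSpec())
    cat = assign_categories(cases["aabc"].to_numpy(), scheme).set_axis(cases.index)
    out_of_window = int(cat.isna().sum())
    if out_of_window:
        logger.info("excluded %d FP cases with AaBC outside 12-168 h", out_of_window)
    cases = cases.loc[cat.notna()]
    cat = cat.loc[cases.index]
    tab = (
        pd.crosstab(cases["disease"], cat)
        .reindex(columns=list(_CATS), fill_value=0)
        .astype(int)
    )
    tab.columns.name = None
    tab.index.name = "disease"
    return FPCountTable(
        counts=tab, neg_sizes=neg_sizes or load_published_neg_sizes()
    )


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def expected_counts(
    observed, neg_sizes, share_decimals: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Expected FP counts if timing had no effect, plus display integers.

    ``expected_i = total * neg_size_i / sum(neg_sizes)``.  With the default
    exact shares the expected counts conserve the observed total.  Published
    screening tables derive expectations from window shares reported at one
    decimal percent; ``share_decimals=3`` reproduces that convention.
    Display form is nearest integer, ties away from zero.
    """
    obs = np.asarray(observed, dtype=float)
    total = obs.sum()
    if total <= 0:
        raise ValueError("expectation undefined for a zero observed total")
    neg = np.asarray(neg_sizes, dtype=float)
    shares = neg / neg.sum()
    if share_decimals is not None:
        shares = np.round(shares, share_decimals)
    expected = total * shares
    return expected, _round_half_away(expected).astype(int)


@dataclass(frozen=True)
class GofResult:
    statistic: float
    p_value: float
    df: int


def gof_test(observed, neg_sizes) -> GofResult:
    """Chi-squared goodness of fit of FP counts against timing-free shares.

    Pearson statistic ``sum((obs - exp)^2 / exp)`` with df = 2.  Emits a
    warning when any expected count falls below 5 (asymptotics doubtful).
    """
    obs = np.asarray(observed, dtype=float)
    expected, _ = expected_counts(obs, neg_sizes)
    if np.any(expected == 0):
        raise ValueError("chi-squared test undefined with a zero expected count")
    if np.any(expected < 5):
        warnings.warn("expected count below 5; chi-squared approximation is doubtful",
                      stacklevel=2)
    stat, p = stats.chisquare(obs, f_exp=expected)
    return GofResult(statistic=float(stat), p_value=float(p), df=len(obs) - 1)


def category_test(observed, neg_sizes, category: str) -> GofResult:
    """One-sample proportion test of one window's FP share vs its negative share.

    Two-cell chi-squared of (obs_i, total - obs_i) against (pi_i, 1 - pi_i)
    where pi_i is the screen-negative share of the window; df = 1, no
    continuity correction.  The screen-negative cohort is ~3 orders of
    magnitude larger than any FP series, so its share is treated as fixed.
    """
    obs = np.asarray(observed, dtype=float)
    total = obs.sum()
    if total <= 0:
        raise ValueError("test undefined for a zero observed total")
    i = _CATS.index(category)
    neg = np.asarray(neg_sizes, dtype=float)
    pi = neg[i] / neg.sum()
    if pi <= 0 or pi >= 1:
        raise ValueError("window share must be strictly between 0 and 1")
    stat, p = stats.chisquare([obs[i], total - obs[i]],
                              f_exp=[total * pi, total * (1 - pi)])
    return GofResult(statistic=float(stat), p_value=float(p), df=1)


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed-vs-expected comparison for one disease."""

    disease: str
    observed: tuple
    expected: tuple
    expected_display: tuple
    gof: GofResult
    category_p: dict  # category -> p
    category_direction: dict  # category -> "excess" | "deficit" | "none"


def enrichment(
    table: FPCountTable, disease: str, share_decimals: int | None = None
) -> EnrichmentResult:
    """Full observed-vs-expected workup for one disease row."""
    obs = table.counts.loc[disease, list(_CATS)].to_numpy(dtype=float)
    expected, display = expected_counts(obs, table.neg_sizes, share_decimals)
    gof = gof_test(obs, table.neg_sizes)
    cat_p, cat_dir = {}, {}
    for i, cat in enumerate(_CATS):
        cat_p[cat] = category_test(obs, table.neg_sizes, cat).p_value
        diff = obs[i] - expected[i]
        cat_dir[cat] = "excess" if diff > 0 else ("deficit" if diff < 0 else "none")
    return EnrichmentResult(
        disease=disease,
        observed=tuple(int(o) for o in obs),
        expected=tuple(expected),
        expected_display=tuple(int(d) for d in display),
        gof=gof,
        category_p=cat_p,
        category_direction=cat_dir,
    )


@dataclass(frozen=True)
class ConsistencyCall:
    """Whether a marker's AaBC shift predicts the FP excess/deficit."""

    disease: str
    category: str
    call: str  # "consistent" | "inconsistent" | "indeterminate"
    rationale: dict


def classify_consistency(
    d: float,
    spec: DiseaseMarkerSpec,
    enr: EnrichmentResult,
    category: str,
    flag_threshold: float = 0.2,
    alpha: float = 0.05,
) -> ConsistencyCall:
    """Consistency of the marker shift with the FP excess/deficit.

    A marker running high in a window (positive screen-negative d) should
    inflate false positives there when the disease is flagged by an elevated
    marker, and deflate them when the disease is flagged by a decreased
    marker — so the predicted sign of (observed - expected) is
    ``sign(d) * (+1 if elevated else -1)``.

    The call is ``consistent`` when the observed deviation has the predicted
    sign *and* the window's proportion test is significant; ``inconsistent``
    whenever the deviation runs against the prediction (significance is
    recorded but not required — an FP deficit where physiology predicts an
    excess contradicts the hypothesis even when the series is too small for
    the test to reject); and ``indeterminate`` when |d| does not exceed the
    flag threshold, the deviation is zero, or the predicted direction holds
    without significance (typically a small FP series).
    """
    i = _CATS.index(category)
    observed_diff = enr.observed[i] - enr.expected[i]
    p = enr.category_p[category]
    rationale = {
        "d": d,
        "marker_direction": spec.direction,
        "observed": enr.observed[i],
        "expected": enr.expected[i],
        "p": p,
    }
    if abs(d) <= flag_threshold or math.isnan(d):
        return ConsistencyCall(spec.disease, category, "indeterminate",
                               {**rationale, "reason": "effect size below flag threshold"})
    predicted = math.copysign(1.0, d) * (1.0 if spec.direction == "elevated" else -1.0)
    if observed_diff == 0:
        return ConsistencyCall(spec.disease, category, "indeterminate",
                               {**rationale, "reason": "no observed deviation"})
    if math.copysign(1.0, observed_diff) == predicted:
        if p < alpha:
            return ConsistencyCall(spec.disease, category, "consistent", rationale)
        return ConsistencyCall(spec.disease, category, "indeterminate",
                               {**rationale, "reason": "predicted direction but not significant"})
    return ConsistencyCall(spec.disease, category, "inconsistent", rationale)


def significance_stars(p: float) -> str:
    """Star tiering: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def share_pct(part: float, whole: float) -> float:
    """Percentage share rounded to one decimal, the table reporting convention."""
    return round(part / whole * 100.0, 1)


def table_report(
    table: FPCountTable,
    marker_info: pd.DataFrame | None = None,
    share_decimals: int | None = 3,
) -> pd.DataFrame:
    """Assemble the per-disease FP summary table.

    One row per disease: observed count with window percentage, expected
    count, significance stars from the per-window proportion test, and —
    when ``marker_info`` provides marker/direction/d columns — the
    consistency call for the early and late windows.

    ``marker_info`` must be indexed by disease with columns ``marker``,
    ``direction``, ``d_early``, ``d_late`` (the layout of
    :func:`load_published_fp_counts`).
    """
    pct = table.percentages()
    rows = []
    for disease in table.counts.index:
        enr = enrichment(table, disease, share_decimals=share_decimals)
        row = {"disease": disease}
        if marker_info is not None and disease in marker_info.index:
            row["marker"] = marker_info.loc[disease, "marker"]
            row["direction"] = marker_info.loc[disease, "direction"]
        for cat in _CATS:
            i = _CATS.index(cat)
            p_str = "—" if np.isnan(pct.loc[disease, cat]) else f"{pct.loc[disease, cat]:.1f}%"
            row[f"obs_{cat}"] = f"{enr.observed[i]} ({p_str})"
            row[f"exp_{cat}"] = enr.expected_display[i]
            row[f"sig_{cat}"] = significance_stars(enr.category_p[cat])
        if marker_info is not None and disease in marker_info.index:
            spec = DiseaseMarkerSpec(
                disease, marker_info.loc[disease, "marker"],
                marker_info.loc[disease, "direction"],
            )
            for cat, col in (("early", "d_early"), ("late", "d_late")):
                d = float(marker_info.loc[disease, col])
                row[f"d_{cat}"] = d
                row[f"call_{cat}"] = classify_consistency(d, spec, enr, cat).call
        rows.append(row)
    return pd.DataFrame(rows).set_index("disease")
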