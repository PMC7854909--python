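"""Cohen's d effect-size profiling of metabolites across AaBC bins.

Group differences in analyte levels between collection windows are measured
with Cohen's d — the difference of two group means divided by the pooled
standard deviation — which is insensitive to the (very unequal) group sizes
of the collection windows.  The per-metabolite d values against the
reference window form an effect-size matrix whose rows are clustered to
separate analytes with decreasing vs increasing postnatal trajectories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .cohort import AaBCScheme, assign_categories, assign_fine_bins

logger = logging.getLogger(__name__)

__all__ = [
    "EffectSizeError",
    "AnalysisConfig",
    "EffectSizeMatrix",
    "ClusterResult",
    "cohen_d",
    "effect_matrix",
    "flag_markers",
    "cluster_profiles",
]


class EffectSizeError(ValueError):
    """Cohen's d is undefined (zero pooled SD) or a group is too small."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds for marker flagging.

    ``flag_threshold`` is the strict |d| cutoff for an AaBC-related
    difference; ``strong_threshold`` marks substantially shifted analytes.
    """

    flag_threshold: float = 0.2
    strong_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.flag_threshold < self.strong_threshold:
            raise ValueError("need 0 < flag_threshold < strong_threshold")


def cohen_d(x, y) -> float:
    """Cohen's d of sample ``x`` versus reference sample ``y``.

    ``d = (mean(x) - mean(y)) / s_pooled`` with the pooled variance
    ``((n_x - 1) s_x^2 + (n_y - 1) s_y^2) / (n_x + n_y - 2)``.  Positive d
    means the comparison group runs higher than the reference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise EffectSizeError(
            f"need at least 2 observations per group (got {x.size} and {y.size})"
        )
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    pooled = ((x.size - 1) * vx + (y.size - 1) * vy) / (x.size + y.size - 2)
    if pooled <= 0:
        raise EffectSizeError("pooled standard deviation is zero")
    return float((x.mean() - y.mean()) / np.sqrt(pooled))


@dataclass(frozen=True)
class EffectSizeMatrix:
    """Metabolites x comparison-bins matrix of Cohen's d values.

    ``values`` has metabolite rows and one column per non-reference bin;
    cells that could not be computed (empty or degenerate bins) are NaN.
    ``group_ns`` counts records per bin (including the reference).
    """

    values: pd.DataFrame
    group_ns: pd.Series
    mode: str
    reference: str

    @property
    def metabolites(self) -> list:
        return list(self.values.index)


def effect_matrix(
    records: pd.DataFrame,
    scheme: AaBCScheme | None = None,
    metabolites: list | None = None,
    mode: str = "fine",
) -> EffectSizeMatrix:
    """Cohen's d of every metabolite in every bin against the reference bin.

    ``mode="fine"`` compares each of the nine 6-h windows 18-72 h to the
    12-17 h window; ``mode="category"`` compares early and late collection
    to the standard window.  Records should already be restricted to the
    reference population.  Empty or single-record bins yield NaN cells,
    logged rather than silently zeroed.
    """
    scheme = scheme or AaBCScheme()
    if mode == "fine":
        bins = assign_fine_bins(records["aabc"].to_numpy(), scheme)
        labels = scheme.fine_labels
        ref_key = scheme.reference_fine
        keys = list(range(len(scheme.fine_bins)))
    elif mode == "category":
        bins = assign_categories(records["aabc"].to_numpy(), scheme)
        labels = scheme.category_names
        ref_key = scheme.reference_category
        keys = scheme.category_names
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if metabolites is None:
        from .cohort import RECORD_COLUMNS

        metabolites = [c for c in records.columns if c not in RECORD_COLUMNS]

    bins = bins.set_axis(records.index)
    groups = {k: records.index[(bins == k).fillna(False)] for k in keys}
    ns = pd.Series({lab: len(groups[k]) for k, lab in zip(keys, labels)}, name="n")
    ref_idx = groups[ref_key]

    cols = [lab for k, lab in zip(keys, labels) if k != ref_key]
    out = pd.DataFrame(np.nan, index=metabolites, columns=cols)
    for met in metabolites:
        ref_vals = records.loc[ref_idx, met].to_numpy()
        for k, lab in zip(keys, labels):
            if k == ref_key:
                continue
            vals = records.loc[groups[k], met].to_numpy()
            try:
                out.loc[met, lab] = cohen_d(vals, ref_vals)
            except EffectSizeError as err:
                logger.warning("effect cell (%s, %s) missing: %s", met, lab, err)
    ref_label = labels[keys.index(ref_key)]
    return EffectSizeMatrix(values=out, group_ns=ns, mode=mode, reference=ref_label)


def flag_markers(matrix: EffectSizeMatrix, config: AnalysisConfig | None = None) -> set:
    """Entries with |d| strictly above the flag threshold.

    Returns a set of ``(metabolite, bin, direction)`` with direction
    ``"elevated"`` (d > 0, the window runs above the reference) or
    ``"decreased"``.
    """
    config = config or AnalysisConfig()
    flagged = set()
    for met in matrix.values.index:
        for col in matrix.values.columns:
            d = matrix.values.loc[met, col]
            if pd.notna(d) and abs(d) > config.flag_threshold:
                flagged.add((met, col, "elevated" if d > 0 else "decreased"))
    return flagged


@dataclass(frozen=True)
class ClusterResult:
    """Two-cluster grouping of metabolite AaBC profiles."""

    linkage: np.ndarray
    labels: dict  # metabolite -> "decreasing" | "increasing"
    order: list  # dendrogram leaf order (metabolite names)
    imputed: tuple = ()


def cluster_profiles(matrix: EffectSizeMatrix) -> ClusterResult:
    """Hierarchically cluster metabolite d-profiles into two trend groups.

    Rows (9-vectors of Cohen's d over the fine bins) are clustered with
    complete linkage on Euclidean distance and cut at two clusters.  The
    cluster whose mean terminal-bin d is lower is labelled ``decreasing``
    (its analytes end below the 12-17 h reference), the other
    ``increasing``.  Missing cells are imputed by within-row linear
    interpolation for clustering only.
    """
    vals = matrix.values.copy()
    if len(vals) < 2:
        raise ValueError("need at least 2 metabolites to cluster")
    imputed = []
    if vals.isna().any().any():
        for met in vals.index[vals.isna().any(axis=1)]:
            imputed.append(met)
            vals.loc[met] = (
                vals.loc[met].astype(float).interpolate(limit_direction="both")
            )
        logger.info("imputed missing cells by row interpolation: %s", imputed)
        if vals.isna().any().any():
            raise ValueError("rows with no finite cells cannot be clustered")

    X = vals.to_numpy()
    if np.allclose(X, X[0]):
        warnings.warn(
            "all metabolite profiles identical; degenerate single cluster",
            stacklevel=2,
        )
        label = "decreasing" if X[0, -1] < 0 else "increasing"
        return ClusterResult(
            linkage=np.empty((0, 4)),
            labels={m: label for m in vals.index},
            order=list(vals.index),
            imputed=tuple(imputed),
        )

    Z = linkage(X, method="complete", metric="euclidean")
    cut = fcluster(Z, t=2, criterion="maxclust")
    terminal = X[:, -1]
    means = {c: terminal[cut == c].mean() for c in np.unique(cut)}
    if len(means) == 1:
        only = next(iter(means))
        name_of = {only: "decreasing" if means[only] < 0 else "increasing"}
    else:
        lo = min(means, key=means.get)
        name_of = {c: ("decreasing" if c == lo else "increasing") for c in means}
    labels = {m: name_of[c] for m, c in zip(vals.index, cut)}
    order = [vals.index[i] for i in leaves_list(Z)]
    return ClusterResult(linkage=Z, labels=labels, order=order, imputed=tuple(imputed))
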