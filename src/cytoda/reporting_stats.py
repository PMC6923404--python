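"""Descriptive outputs (heat-map matrices, dendrograms, dot-plot samples)
and cohort-level statistics (Fisher's exact test, pooled two-sample t)."""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import pdist

from .clustering import ClusterAssignment
from .fcs_io import ValidationError

__all__ = [
    "HeatmapMatrix",
    "heatmap_matrix",
    "dotplot_sample",
    "fisher_exact_2x2",
    "two_sample_t",
]


@dataclass
class HeatmapMatrix:
    """Mean-expression matrix with hierarchical-clustering merge trees."""

    matrix: pd.DataFrame
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


def heatmap_matrix(
    expr: pd.DataFrame, group_by: np.ndarray, use_median: bool = False
) -> HeatmapMatrix:
    """Mean (or median) arcsinh expression per grouping unit, with
    average-linkage Euclidean dendrograms over rows and columns.

    Empty grouping units cannot occur (group_by is per event); units and
    markers with fewer than two members get no dendrogram.
    """
    df = expr.copy()
    df["_g"] = np.asarray(group_by)
    agg = df.groupby("_g").median() if use_median else df.groupby("_g").mean()
    agg.index.name = None
    if not np.all(np.isfinite(agg.to_numpy())):
        raise ValidationError("non-finite values in heat-map matrix")
    row_link = average(pdist(agg.to_numpy())) if agg.shape[0] > 1 else None
    col_link = average(pdist(agg.to_numpy().T)) if agg.shape[1] > 1 else None
    return HeatmapMatrix(matrix=agg, row_linkage=row_link, col_linkage=col_link)


def dotplot_sample(
    expr: pd.DataFrame,
    assignment: ClusterAssignment | np.ndarray,
    cluster,
    n: int = 256,
    seed: int = 0,
    level: str = "lineage",
) -> pd.DataFrame:
    """Seeded uniform subsample (without replacement) of one cluster's
    events with their expression values attached."""
    if isinstance(assignment, ClusterAssignment):
        labels = assignment.table[level].to_numpy()
    else:
        labels = np.asarray(assignment)
    idx = np.flatnonzero(labels == cluster)
    if idx.size == 0:
        raise ValidationError(f"cluster {cluster!r} is empty")
    rng = np.random.default_rng(seed)
    if idx.size > n:
        idx = np.sort(rng.choice(idx, size=n, replace=False))
    out = expr.iloc[idx].copy()
    out.insert(0, "event_index", idx)
    out.insert(1, "cluster", cluster)
    return out.reset_index(drop=True)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    The two-sided rule is the point-probability method: sum the
    hypergeometric probabilities of all tables with the observed margins
    whose point probability does not exceed that of the observed table.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ValidationError("expected a 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if min(a, b, c, d) < 0:
        raise ValidationError("cells must be non-negative")
    if a + b + c + d == 0:
        raise ValidationError("at least one cell must be positive")
    r1, r2, c1 = a + b, c + d, a + c
    # integer hypergeometric weights: w(k) = C(r1,k) C(r2,c1-k); the p-value
    # is the weight fraction of tables no more probable than the observed one
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = w[a]
    num = sum(wk for wk in w.values() if wk <= w_obs)
    return float(num / sum(w.values()))


def two_sample_t(x=None, y=None, summary=None):
    """Pooled-variance two-sample t test, two-sided.

    Either raw samples ``x`` and ``y`` or ``summary`` =
    (mean1, sd1, n1, mean2, sd2, n2). Returns (t, df, p).
    """
    if summary is not None:
        m1, s1, n1, m2, s2, n2 = summary
    else:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        m1, s1, n1 = x.mean(), x.std(ddof=1), x.size
        m2, s2, n2 = y.mean(), y.std(ddof=1), y.size
    if n1 < 2 or n2 < 2:
        raise ValidationError("need at least 2 observations per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 <= 0:
        raise ValidationError("zero pooled variance")
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)
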