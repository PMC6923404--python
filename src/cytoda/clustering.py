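"""Two-level population identification: batch self-organizing map,
consensus hierarchical meta-clustering, lineage merging, within-lineage
subclustering and per-sample frequency tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist, squareform

from .fcs_io import ValidationError

__all__ = [
    "ClusterModel",
    "ClusterAssignment",
    "fit_som",
    "consensus_metacluster",
    "choose_k_and_merge",
    "subcluster",
    "cluster_frequencies",
]

UNIDENTIFIED = "unidentified"


@dataclass
class ClusterModel:
    """Fitted SOM codebook plus consensus meta-clustering results."""

    codebook: np.ndarray
    grid_shape: tuple
    channels_used: list
    seed: int
    node_of_event: np.ndarray | None = None
    node_to_meta: dict = field(default_factory=dict)   # k -> node -> meta id (1..k)
    consensus: dict = field(default_factory=dict)      # k -> node x node matrix

    @property
    def n_nodes(self) -> int:
        return self.codebook.shape[0]

    def meta_of_event(self, k: int) -> np.ndarray:
        if k not in self.node_to_meta:
            raise ValidationError(f"no meta-clustering at k={k}; run consensus first")
        return self.node_to_meta[k][self.node_of_event]


@dataclass
class ClusterAssignment:
    """Per-event labels: sample, lineage and optional subcluster."""

    table: pd.DataFrame  # columns: sample_id, lineage, (subcluster)
    merge_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"sample_id", "lineage"}
        if not need <= set(self.table.columns):
            raise ValidationError(f"assignment table needs columns {sorted(need)}")
        if "subcluster" in self.table.columns:
            bad = self.table["subcluster"].notna() & self.table["lineage"].isna()
            if bad.any():
                raise ValidationError("event with subcluster but no lineage")

    @property
    def identified(self) -> pd.DataFrame:
        return self.table[self.table["lineage"] != UNIDENTIFIED]


# ---------------------------------------------------------------------------
# batch SOM
# ---------------------------------------------------------------------------

def _principal_plane_init(X: np.ndarray, grid_shape: tuple) -> np.ndarray:
    """Initialize the codebook on the grid spanned by the first two PCs."""
    rows, cols = grid_shape
    mu = X.mean(axis=0)
    Xc = X - mu
    # deterministic PCA via SVD with a fixed sign convention
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(min(2, Vt.shape[0])):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
    n = X.shape[0]
    sd = s / np.sqrt(max(n - 1, 1))
    r = np.linspace(-1, 1, rows) if rows > 1 else np.zeros(1)
    c = np.linspace(-1, 1, cols) if cols > 1 else np.zeros(1)
    rr, cc = np.meshgrid(r, c, indexing="ij")
    # PC1 spans the longer grid dimension
    first, second = (rr, cc) if rows >= cols else (cc, rr)
    code = np.tile(mu, (rows * cols, 1)).astype(float)
    if Vt.shape[0] >= 1:
        code += 2 * sd[0] * first.ravel()[:, None] * Vt[0]
    if Vt.shape[0] >= 2 and min(rows, cols) > 1:
        code += 2 * sd[1] * second.ravel()[:, None] * Vt[1]
    return code


def _bmu(X: np.ndarray, codebook: np.ndarray, chunk: int = 65536) -> np.ndarray:
    """Best-matching node per event by Euclidean distance."""
    out = np.empty(X.shape[0], dtype=int)
    cb_sq = (codebook**2).sum(axis=1)
    for s in range(0, X.shape[0], chunk):
        blk = X[s : s + chunk]
        d = blk @ codebook.T
        d *= -2.0
        d += cb_sq
        out[s : s + chunk] = np.argmin(d, axis=1)
    return out


def fit_som(
    X: np.ndarray,
    grid_shape: tuple = (10, 10),
    seed: int = 0,
    channels_used: list | None = None,
    epochs: int = 10,
) -> ClusterModel:
    """Train a batch SOM and map every event to its best-matching node.

    Principal-plane initialization, Gaussian neighborhood with radius
    shrinking linearly from half the grid diagonal to 1 over ``epochs``
    batch updates. Fully deterministic given the data.
    """
    X = np.asarray(X, float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("NaN/inf in clustering input")
    rows, cols = grid_shape
    n_nodes = rows * cols
    if X.shape[0] < n_nodes:
        raise ValidationError(
            f"need at least {n_nodes} events for a {rows}x{cols} grid, got {X.shape[0]}"
        )
    codebook = _principal_plane_init(X, grid_shape)

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    grid_pos = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    grid_d2 = squareform(pdist(grid_pos)) ** 2

    r0 = 0.5 * np.hypot(rows - 1, cols - 1)
    r0 = max(r0, 1.0)
    for e in range(epochs):
        radius = r0 + (1.0 - r0) * (e / max(epochs - 1, 1))
        h = np.exp(-grid_d2 / (2.0 * radius**2))
        bmu = _bmu(X, codebook)
        counts = np.bincount(bmu, minlength=n_nodes).astype(float)
        sums = np.zeros_like(codebook)
        np.add.at(sums, bmu, X)
        num = h @ sums
        den = (h @ counts)[:, None]
        upd = den[:, 0] > 0
        codebook[upd] = num[upd] / den[upd]

    node = _bmu(X, codebook)
    return ClusterModel(
        codebook=codebook,
        grid_shape=tuple(grid_shape),
        channels_used=list(channels_used or []),
        seed=seed,
        node_of_event=node,
    )


# ---------------------------------------------------------------------------
# consensus meta-clustering
# ---------------------------------------------------------------------------

def _hclust_cut(D_condensed: np.ndarray, k: int) -> np.ndarray:
    Z = average(D_condensed)
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_metacluster(
    model: ClusterModel,
    max_k: int = 25,
    n_resample: int = 100,
    subsample_frac: float = 0.9,
    seed: int | None = None,
) -> ClusterModel:
    """Fill ``node_to_meta`` and ``consensus`` for k = 2..max_k.

    For each k: repeatedly subsample codebook rows, average-linkage
    hierarchical clustering cut at k, and record co-clustering fractions;
    the final partition cuts average-linkage clustering of
    (1 - consensus) at k.
    """
    n = model.n_nodes
    if max_k >= n:
        raise ValidationError(f"max_k={max_k} must be below node count {n}")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    m = int(np.ceil(subsample_frac * n))

    subsets = [rng.choice(n, size=m, replace=False) for _ in range(n_resample)]
    dists = [pdist(model.codebook[idx]) for idx in subsets]
    co_sampled = np.zeros((n, n))
    for idx in subsets:
        co_sampled[np.ix_(idx, idx)] += 1.0

    for k in range(2, max_k + 1):
        co_cluster = np.zeros((n, n))
        for idx, d in zip(subsets, dists):
            lab = _hclust_cut(d, k)
            same = lab[:, None] == lab[None, :]
            co_cluster[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(co_sampled > 0, co_cluster / co_sampled, 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = 0.5 * (cons + cons.T)
        model.consensus[k] = cons
        final = _hclust_cut(squareform(1.0 - cons, checks=False), k)
        model.node_to_meta[k] = np.asarray(final, int)
    return model


def choose_k_and_merge(
    model: ClusterModel, k: int, merge_map: dict, sample_ids: np.ndarray
) -> ClusterAssignment:
    """Map events through node -> metacluster -> lineage label.

    ``merge_map`` must cover every metacluster id at the chosen k; the
    reserved lineage name ``unidentified`` marks events excluded from
    downstream analysis (they stay in the table and are counted).
    """
    meta = model.meta_of_event(k)
    present = sorted(set(np.unique(model.node_to_meta[k])))
    missing = [m for m in present if m not in merge_map]
    if missing:
        raise ValidationError(f"merge_map does not cover metaclusters: {missing}")
    lineage = np.array([merge_map[m] for m in meta], dtype=object)
    table = pd.DataFrame({"sample_id": np.asarray(sample_ids), "lineage": lineage})
    return ClusterAssignment(table=table, merge_map=dict(merge_map))


def subcluster(
    X: np.ndarray,
    sample_ids: np.ndarray,
    k: int,
    grid_shape: tuple = (7, 7),
    seed: int = 0,
    min_mean_pct_of_parent: float = 0.1,
    consensus_kwargs: dict | None = None,
    lineage: str = "",
) -> np.ndarray:
    """Second-level clustering of one lineage's events.

    Runs SOM + consensus on the lineage events, cuts at ``k``, then merges
    any cluster whose mean per-sample frequency is below
    ``min_mean_pct_of_parent`` percent into the nearest retained cluster
    (codebook-centroid Euclidean distance). Returns integer labels (1-based).
    """
    X = np.asarray(X, float)
    if X.shape[0] < 200:
        raise ValidationError(
            f"lineage {lineage or '?'}: {X.shape[0]} events < 200 minimum"
        )
    n_nodes = grid_shape[0] * grid_shape[1]
    model = fit_som(X, grid_shape=grid_shape, seed=seed)
    if k == 1:
        return np.ones(X.shape[0], dtype=int)
    model = consensus_metacluster(
        model, max_k=min(max(k, 2), n_nodes - 1), **(consensus_kwargs or {})
    )
    labels = model.meta_of_event(k)

    sample_ids = np.asarray(sample_ids)
    samples = np.unique(sample_ids)
    # mean across samples of per-sample % of parent
    clusters = np.unique(labels)
    mean_pct = {}
    for c in clusters:
        pcts = []
        for s in samples:
            in_s = sample_ids == s
            tot = in_s.sum()
            pcts.append(100.0 * np.sum(in_s & (labels == c)) / tot if tot else 0.0)
        mean_pct[c] = float(np.mean(pcts)) if len(pcts) else 0.0

    centroids = {c: X[labels == c].mean(axis=0) for c in clusters}
    small = [c for c in clusters if mean_pct[c] < min_mean_pct_of_parent]
    retained = [c for c in clusters if c not in small]
    if retained:
        for c in small:
            d = [float(np.linalg.norm(centroids[c] - centroids[r])) for r in retained]
            target = retained[int(np.argmin(d))]
            labels[labels == c] = target
    # relabel to consecutive 1..K preserving order
    remap = {c: i + 1 for i, c in enumerate(sorted(np.unique(labels)))}
    return np.array([remap[c] for c in labels], dtype=int)


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def cluster_frequencies(assignment: ClusterAssignment, metadata) -> pd.DataFrame:
    """Per (sample, cluster) counts with % of parent and % of total.

    For lineages, parent = all identified events of the sample; for
    subclusters, parent = the lineage's events in that sample. Zero-count
    pairs are materialized explicitly.
    """
    meta_ids = set(metadata.sample_ids)
    tab = assignment.table
    missing = sorted(set(tab["sample_id"].unique()) - meta_ids)
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")

    ident = assignment.identified
    samples = list(metadata.sample_ids)
    lineages = sorted(ident["lineage"].unique())
    total_per_sample = ident.groupby("sample_id").size()

    rows = []
    has_sub = "subcluster" in tab.columns and ident["subcluster"].notna().any()
    for s in samples:
        sub_tab = ident[ident["sample_id"] == s]
        n_tot = int(total_per_sample.get(s, 0))
        for lin in lineages:
            lin_tab = sub_tab[sub_tab["lineage"] == lin]
            n_lin = len(lin_tab)
            rows.append(
                {
                    "sample_id": s,
                    "lineage": lin,
                    "subcluster": "",
                    "count": n_lin,
                    "pct_of_parent": 100.0 * n_lin / n_tot if n_tot else 0.0,
                    "pct_of_total": 100.0 * n_lin / n_tot if n_tot else 0.0,
                }
            )
            if has_sub:
                subs = sorted(
                    ident[ident["lineage"] == lin]["subcluster"].dropna().unique()
                )
                for sc in subs:
                    n_sc = int((lin_tab["subcluster"] == sc).sum())
                    rows.append(
                        {
                            "sample_id": s,
                            "lineage": lin,
                            "subcluster": str(sc),
                            "count": n_sc,
                            "pct_of_parent": 100.0 * n_sc / n_lin if n_lin else 0.0,
                            "pct_of_total": 100.0 * n_sc / n_tot if n_tot else 0.0,
                        }
                    )
    return pd.DataFrame(rows)
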