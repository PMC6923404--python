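"""2-D t-SNE embedding of pooled events, equal-frequency binning of the
map, and bin-wise negative-binomial differential-abundance testing.

The count model is an edgeR-flavoured NB GLM with a log link, per-sample
library-size offsets, a single common dispersion estimated by profile
likelihood, and a likelihood-ratio test of the group effect per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import minimize_scalar

from .cluster_da import adjust_bh
from .fcs_io import ValidationError

__all__ = [
    "TsneParams",
    "EmbeddingResult",
    "BinPartition",
    "embed_tsne",
    "bin_embedding",
    "estimate_common_dispersion",
    "test_bins",
    "da_map_export",
]


@dataclass
class TsneParams:
    perplexity: float = 30.0
    theta: float = 0.5
    iterations_per_100k: int = 1000
    min_iterations: int = 1000
    max_iterations: int | None = None  # override for tests

    def n_iter(self, n_events: int) -> int:
        if self.max_iterations is not None:
            return self.max_iterations
        return max(
            self.min_iterations,
            int(np.ceil(self.iterations_per_100k * n_events / 100_000)),
        )


@dataclass
class EmbeddingResult:
    coords: np.ndarray
    params: TsneParams
    seed: int
    channels_used: list = field(default_factory=list)


def embed_tsne(
    X: np.ndarray,
    params: TsneParams | None = None,
    seed: int = 0,
    channels_used: list | None = None,
) -> EmbeddingResult:
    """Barnes-Hut t-SNE of arcsinh-scale expression values.

    Iteration count follows the 1000-per-100,000-events rule with a floor
    of 1000. Deterministic for a given seed.
    """
    from sklearn.manifold import TSNE

    params = params or TsneParams()
    X = np.asarray(X, float)
    n = X.shape[0]
    if n < 3 * params.perplexity:
        raise ValidationError(
            f"{n} events < 3 x perplexity ({params.perplexity}); lower the perplexity"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=params.perplexity,
        angle=params.theta,
        max_iter=params.n_iter(n),
        init="pca",
        method="barnes_hut",
        random_state=seed,
    )
    coords = np.asarray(tsne.fit_transform(X), float)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("t-SNE produced non-finite coordinates")
    return EmbeddingResult(
        coords=coords, params=params, seed=seed, channels_used=list(channels_used or [])
    )


# ---------------------------------------------------------------------------
# equal-frequency binning
# ---------------------------------------------------------------------------

@dataclass
class BinPartition:
    depth: int
    bin_of_event: np.ndarray
    splits: list  # (node path, axis, threshold) per internal node

    @property
    def n_bins(self) -> int:
        return 2**self.depth


def bin_embedding(coords: np.ndarray, depth: int = 8) -> BinPartition:
    """Recursive equal-frequency median splits of the 2-D map.

    At each node the axis with the larger spread is split at its median;
    rank ties resolve by original event order (stable sort), so the two
    children differ in size by at most one event. Deterministic.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    if n < 2**depth:
        raise ValidationError(f"{n} events cannot fill 2^{depth} bins")

    bin_of_event = np.zeros(n, dtype=int)
    splits: list[tuple] = []

    def rec(idx: np.ndarray, level: int, path: int) -> None:
        if level == depth:
            bin_of_event[idx] = path
            return
        pts = coords[idx]
        spread = pts.max(axis=0) - pts.min(axis=0)
        axis = int(np.argmax(spread))
        order = np.argsort(pts[:, axis], kind="stable")
        n_left = (len(idx) + 1) // 2
        left, right = idx[order[:n_left]], idx[order[n_left:]]
        thr = float(pts[order[n_left - 1], axis])
        splits.append((path, level, axis, thr))
        rec(left, level + 1, path << 1)
        rec(right, level + 1, (path << 1) | 1)

    rec(np.arange(n), 0, 0)
    return BinPartition(depth=depth, bin_of_event=bin_of_event, splits=splits)


# ---------------------------------------------------------------------------
# negative-binomial GLM testing
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 log-likelihood (sans y! constant), elementwise; size = 1/alpha."""
    r = 1.0 / alpha
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def _fit_nb_means(
    Y: np.ndarray, offs: np.ndarray, X: np.ndarray, alpha: float, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher-scoring NB GLM fits for all bins at once.

    Y: bins x samples counts; offs: log library sizes (samples,);
    X: samples x p design shared by all bins. Returns (beta: bins x p,
    loglik per bin).
    """
    B, S = Y.shape
    p = X.shape[1]
    # init: log of overall rate
    rate = (Y.sum(axis=1) + 0.5) / np.exp(offs).sum()
    beta = np.zeros((B, p))
    beta[:, 0] = np.log(rate)
    for _ in range(n_iter):
        eta = beta @ X.T + offs  # B x S
        eta = np.clip(eta, -50, 50)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)          # B x S working weights
        z = Y - mu                            # score residual numerator
        # score: X' (z * W / mu) ; info: X' diag(W) X  per bin
        U = (z * W / mu) @ X                  # B x p
        XtWX = np.einsum("bs,sp,sq->bpq", W, X, X)
        try:
            step = np.linalg.solve(XtWX, U[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            XtWX += 1e-8 * np.eye(p)
            step = np.linalg.solve(XtWX, U[:, :, None])[:, :, 0]
        beta += np.clip(step, -5, 5)
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(beta @ X.T + offs, -50, 50)
    mu = np.exp(eta)
    ll = _nb_loglik(Y, np.maximum(mu, 1e-300), alpha).sum(axis=1)
    return beta, ll


def estimate_common_dispersion(
    Y: np.ndarray, lib_sizes: np.ndarray, X: np.ndarray | None = None
) -> float:
    """Common NB dispersion maximizing the profile likelihood across bins.

    Bin-wise mean parameters are re-fitted (profiled out) at every
    candidate dispersion; the 1-D search runs on log-dispersion.
    """
    Y = np.asarray(Y, float)
    offs = np.log(np.asarray(lib_sizes, float))
    if X is None:
        X = np.ones((Y.shape[1], 1))

    def neg_profile(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        _, ll = _fit_nb_means(Y, offs, X, alpha, n_iter=25)
        return -float(ll.sum())

    res = minimize_scalar(neg_profile, bounds=(-8.0, 3.0), method="bounded")
    return float(np.exp(res.x))


@dataclass
class BinDAResult:
    table: pd.DataFrame       # per-bin statistics
    dispersion: float
    fdr_level: float
    counts: pd.DataFrame      # bins x samples


def test_bins(
    partition: BinPartition,
    sample_of_event: np.ndarray,
    metadata,
    fdr: float = 0.10,
    groups: tuple | None = None,
    min_events_per_bin: int = 0,
) -> BinDAResult:
    """NB-GLM differential abundance per bin between two groups.

    Library size = each sample's total event count; common dispersion by
    profile likelihood; per-bin likelihood-ratio test of the group
    coefficient; Benjamini-Hochberg adjustment at ``fdr``.
    """
    sample_of_event = np.asarray(sample_of_event)
    samples = list(metadata.sample_ids)
    group_of = metadata.groups
    if groups is None:
        groups = tuple(pd.unique(group_of.loc[samples]))
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    samples = [s for s in samples if group_of[s] in groups]
    for g in groups:
        if sum(group_of[s] == g for s in samples) < 2:
            raise ValidationError(f"group {g!r} has < 2 samples")

    n_bins = partition.n_bins
    sample_pos = {s: j for j, s in enumerate(samples)}
    Y = np.zeros((n_bins, len(samples)))
    for b, s in zip(partition.bin_of_event, sample_of_event):
        j = sample_pos.get(s)
        if j is not None:
            Y[b, j] += 1
    lib = Y.sum(axis=0)
    if (lib == 0).any():
        raise ValidationError("a sample has zero events in the embedding")

    tested = np.flatnonzero(Y.sum(axis=1) >= max(min_events_per_bin, 0))
    g_ind = np.array([1.0 if group_of[s] == groups[1] else 0.0 for s in samples])
    X_full = np.column_stack([np.ones(len(samples)), g_ind])
    X_null = np.ones((len(samples), 1))

    alpha = estimate_common_dispersion(Y[tested], lib, X_full)
    offs = np.log(lib)
    beta_full, ll_full = _fit_nb_means(Y[tested], offs, X_full, alpha)
    _, ll_null = _fit_nb_means(Y[tested], offs, X_null, alpha)

    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    pvals = stats.chi2.sf(lrt, df=1)
    p_all = np.full(n_bins, np.nan)
    p_all[tested] = pvals
    p_adj, flags = adjust_bh(p_all, level=fdr)

    lfc = np.full(n_bins, np.nan)
    lfc[tested] = beta_full[:, 1] / np.log(2.0)

    mean_counts = {}
    for gi, g in enumerate(groups):
        cols = np.array([group_of[s] == g for s in samples])
        with np.errstate(invalid="ignore"):
            mean_counts[g] = (Y[:, cols] / lib[cols]).mean(axis=1)

    table = pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "n_events": Y.sum(axis=1).astype(int),
            f"mean_frac_{groups[0]}": mean_counts[groups[0]],
            f"mean_frac_{groups[1]}": mean_counts[groups[1]],
            "log2_fold_change": lfc,
            "p": p_all,
            "p_adj": p_adj,
            "significant": flags,
        }
    )
    counts = pd.DataFrame(Y, columns=samples)
    counts.insert(0, "bin", np.arange(n_bins))
    return BinDAResult(table=table, dispersion=alpha, fdr_level=fdr, counts=counts)


def da_map_export(result: BinDAResult, partition: BinPartition, coords: np.ndarray) -> pd.DataFrame:
    """Per-event table of embedding coordinates and the event's bin p_adj."""
    coords = np.asarray(coords, float)
    if coords.shape[0] != partition.bin_of_event.shape[0]:
        raise ValidationError("coords and partition are not aligned")
    p_adj = result.table.set_index("bin")["p_adj"].to_numpy()
    return pd.DataFrame(
        {
            "tsne1": coords[:, 0],
            "tsne2": coords[:, 1],
            "bin": partition.bin_of_event,
            "p_adj": p_adj[partition.bin_of_event],
        }
    )
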