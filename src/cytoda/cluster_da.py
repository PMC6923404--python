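"""Cluster-level differential abundance between groups.

The workhorse is a binomial generalized linear mixed model per cluster:
logit P(cell in cluster | sample) = b0 + b_g * group + u_sample with
u_sample ~ N(0, sigma^2), fitted by maximizing the marginal likelihood with
adaptive Gauss-Hermite quadrature (each sample contributes one binomial
observation, so the random intercept is observation-level and absorbs
overdispersion). Two-group comparisons use a Wald test of b_g; the
three-group omnibus uses a 2-df likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .fcs_io import ValidationError

__all__ = [
    "ClusterCounts",
    "ClusterDAResult",
    "adjust_bh",
    "filter_clusters",
    "fit_binomial_glmm",
    "test_clusters_glmm",
    "presence_filter",
    "test_multi_group",
    "discriminating_markers",
]


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def adjust_bh(p_values, level: float = 0.10):
    """Benjamini-Hochberg step-up adjusted p-values and significance flags.

    NaN entries are excluded from the family (they stay NaN, flag False).
    """
    p = np.asarray(p_values, float)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    adj = np.full(p.shape, np.nan)
    pv = p[mask]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        adj[mask] = out
    flags = np.zeros(p.shape, bool)
    flags[mask] = adj[mask] <= level
    return adj, flags


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ClusterCounts:
    """clusters x samples counts with per-sample parent totals and groups."""

    counts: pd.DataFrame          # index = cluster, columns = sample_id
    totals: pd.Series             # per-sample parent totals
    groups: pd.Series             # per-sample group label

    def __post_init__(self) -> None:
        samples = list(self.counts.columns)
        self.totals = self.totals.loc[samples]
        self.groups = self.groups.loc[samples]
        c = self.counts.to_numpy()
        if (c < 0).any():
            raise ValidationError("negative counts")
        if (c > self.totals.to_numpy()[None, :]).any():
            raise ValidationError("counts exceed per-sample totals")

    @property
    def samples(self) -> list:
        return list(self.counts.columns)


@dataclass
class ClusterDAResult:
    table: pd.DataFrame
    fdr_level: float
    p_threshold: float


def filter_clusters(
    counts: ClusterCounts, min_cells: int = 3, min_samples: float | None = None
):
    """Keep clusters with >= min_cells cells in >= min_samples samples.

    ``min_samples`` defaults to half the number of samples. Returns
    (filtered ClusterCounts, list of removed cluster ids).
    """
    n_samples = len(counts.samples)
    if min_samples is None:
        min_samples = n_samples / 2.0
    ok_per_cluster = (counts.counts >= min_cells).sum(axis=1)
    keep = ok_per_cluster >= min_samples
    removed = list(counts.counts.index[~keep])
    if not keep.any():
        raise ValidationError("filter_clusters removed every cluster")
    return (
        ClusterCounts(counts.counts.loc[keep], counts.totals, counts.groups),
        removed,
    )


# ---------------------------------------------------------------------------
# binomial GLMM by adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(20)


def _marginal_nll(params, y, n, X):
    """Negative marginal log-likelihood (binomial constant dropped).

    params = (beta..., log_sigma); the random effect is integrated out per
    observation with quadrature adapted at the conditional mode.
    """
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(np.clip(log_sigma, -12.0, 4.0))
    offset = X @ beta

    # conditional mode z* per observation (Newton on the standardized scale)
    z = np.zeros_like(offset)
    for _ in range(50):
        eta = offset + sigma * z
        p = special.expit(eta)
        g = sigma * (y - n * p) - z
        h = sigma**2 * n * p * (1.0 - p) + 1.0
        step = g / h
        z += step
        if np.max(np.abs(step)) < 1e-12:
            break
    eta = offset + sigma * z
    p = special.expit(eta)
    h = sigma**2 * n * p * (1.0 - p) + 1.0
    s = 1.0 / np.sqrt(h)

    def f(zz):
        e = offset[:, None] + sigma * zz
        return y[:, None] * e - n[:, None] * np.logaddexp(0.0, e) - 0.5 * zz**2

    zz = z[:, None] + np.sqrt(2.0) * s[:, None] * _GH_NODES[None, :]
    f0 = f(z[:, None])
    integrand = f(zz) - f0 + _GH_NODES[None, :] ** 2 + np.log(_GH_WEIGHTS)[None, :]
    log_int = special.logsumexp(integrand, axis=1)
    ll = f0[:, 0] + np.log(np.sqrt(2.0) * s) - 0.5 * np.log(2.0 * np.pi) + log_int
    return -float(ll.sum())


def fit_binomial_glmm(y, n, X, start_sigma: float = 0.3):
    """Fit the binomial GLMM; returns dict with beta, covariance, sigma,
    loglik and a convergence flag."""
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    X = np.asarray(X, float)
    p_dim = X.shape[1]

    prop = (y.sum() + 0.5) / (n.sum() + 1.0)
    x0 = np.zeros(p_dim + 1)
    x0[0] = np.log(prop / (1.0 - prop))
    x0[-1] = np.log(start_sigma)

    res = optimize.minimize(
        _marginal_nll, x0, args=(y, n, X), method="BFGS",
        options={"gtol": 1e-7, "maxiter": 500},
    )
    if not np.isfinite(res.fun) or np.linalg.norm(res.jac) > 1e-2:
        res = optimize.minimize(
            _marginal_nll, res.x if np.all(np.isfinite(res.x)) else x0,
            args=(y, n, X), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 4000},
        )
    converged = bool(np.isfinite(res.fun))

    # numerical Hessian over the fixed effects (central differences)
    hstep = 1e-4 * np.maximum(np.abs(res.x[:p_dim]), 1.0)
    H = np.zeros((p_dim, p_dim))
    base = res.x.copy()
    for i in range(p_dim):
        for j in range(i, p_dim):
            pts = []
            for si in (1, -1):
                for sj in (1, -1):
                    q = base.copy()
                    q[i] += si * hstep[i]
                    q[j] += sj * hstep[j]
                    pts.append(si * sj * _marginal_nll(q, y, n, X))
            H[i, j] = H[j, i] = sum(pts) / (4.0 * hstep[i] * hstep[j])
    try:
        cov = np.linalg.inv(H)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            converged = False
            cov = np.full((p_dim, p_dim), np.nan)
    except np.linalg.LinAlgError:
        converged = False
        cov = np.full((p_dim, p_dim), np.nan)

    return {
        "beta": res.x[:p_dim],
        "cov": cov,
        "sigma": float(np.exp(np.clip(res.x[-1], -12.0, 4.0))),
        "loglik": -float(res.fun),
        "converged": converged,
    }


def _design(groups: pd.Series, order: list) -> np.ndarray:
    g = np.asarray(groups)
    cols = [np.ones(len(g))]
    for lvl in order[1:]:
        cols.append((g == lvl).astype(float))
    return np.column_stack(cols)


def test_clusters_glmm(
    counts: ClusterCounts,
    fdr: float = 0.10,
    p_threshold: float = 0.05,
    groups: tuple | None = None,
) -> ClusterDAResult:
    """Two-group Wald test of the group effect per cluster, BH-adjusted.

    ``significant`` requires both an adjusted p <= ``fdr`` and a raw
    p < ``p_threshold``; the final ``differential`` flag additionally needs
    the presence criterion (see :func:`presence_filter`).
    """
    order = list(groups) if groups else list(pd.unique(counts.groups))
    if len(order) != 2:
        raise ValidationError(f"expected 2 groups, got {order}")
    for g in order:
        if (counts.groups == g).sum() < 2:
            raise ValidationError(f"group {g!r} has < 2 samples")
    X = _design(counts.groups, order)
    n = counts.totals.to_numpy(float)
    if (n <= 0).any():
        raise ValidationError("per-sample totals must be > 0")
    # small-sample corrections: ML underestimates the random-effect
    # variance, so Wald SEs get a REML-style N/(N-p) inflation and the
    # reference distribution is t with N-p degrees of freedom
    n_obs, p_dim = len(counts.samples), X.shape[1]
    wald_df = n_obs - p_dim
    se_inflation = np.sqrt(n_obs / wald_df)

    rows = []
    for cluster, y in counts.counts.iterrows():
        fit = fit_binomial_glmm(y.to_numpy(float), n, X)
        if fit["converged"]:
            beta_g = fit["beta"][1]
            se = float(np.sqrt(fit["cov"][1, 1])) * se_inflation
            z = beta_g / se if se > 0 else np.nan
            p = 2.0 * stats.t.sf(abs(z), wald_df) if np.isfinite(z) else np.nan
        else:
            beta_g, se, p = np.nan, np.nan, np.nan
        rows.append(
            {
                "cluster": cluster,
                "log_odds_effect": beta_g,
                "se": se,
                "sigma": fit["sigma"],
                "p": p,
                "unstable": not fit["converged"],
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"], bh_flags = adjust_bh(table["p"].to_numpy(), level=fdr)
    table["significant"] = bh_flags & (table["p"].to_numpy() < p_threshold)
    table["differential"] = table["significant"]  # finalized by presence_filter
    if table["unstable"].any():
        import warnings

        warnings.warn(
            f"{int(table['unstable'].sum())} cluster(s) failed to converge; "
            "excluded from the FDR family",
            stacklevel=2,
        )
    return ClusterDAResult(table=table, fdr_level=fdr, p_threshold=p_threshold)


def presence_filter(
    counts: ClusterCounts,
    result: ClusterDAResult,
    threshold: float = 0.80,
    mode: str = "either",
    min_cells: int = 3,
) -> ClusterDAResult:
    """Finalize differential flags with the presence criterion.

    A cluster is "present" in a sample when its count >= ``min_cells``; the
    flag survives only if the presence fraction reaches ``threshold`` in
    each group (mode="each") or at least one group (mode="either").
    """
    if mode not in ("either", "each"):
        raise ValidationError(f"mode must be 'either' or 'each', got {mode!r}")
    groups = list(pd.unique(counts.groups))
    present = counts.counts >= min_cells
    frac = {
        g: present.loc[:, counts.groups[counts.groups == g].index].mean(axis=1)
        for g in groups
    }
    table = result.table.copy()
    for g in groups:
        table[f"presence_{g}"] = table["cluster"].map(frac[g]).to_numpy()
    pres_cols = np.column_stack([table[f"presence_{g}"] for g in groups])
    ok = (
        (pres_cols >= threshold).any(axis=1)
        if mode == "either"
        else (pres_cols >= threshold).all(axis=1)
    )
    table["differential"] = table["significant"].to_numpy() & ok
    return ClusterDAResult(
        table=table, fdr_level=result.fdr_level, p_threshold=result.p_threshold
    )


def test_multi_group(
    counts: ClusterCounts, fdr: float = 0.10, groups: tuple | None = None
):
    """Omnibus group test per cluster plus unadjusted pairwise contrasts.

    With three groups: 2-df likelihood-ratio test of the group factor with
    BH across clusters, and Wald contrasts for every group pair reported
    alongside, unadjusted. With two groups this reduces to
    :func:`test_clusters_glmm`.
    """
    order = list(groups) if groups else list(pd.unique(counts.groups))
    if len(order) == 2:
        return test_clusters_glmm(counts, fdr=fdr, groups=tuple(order))
    for g in order:
        if (counts.groups == g).sum() < 2:
            raise ValidationError(f"group {g!r} has < 2 samples")
    X_full = _design(counts.groups, order)
    X_null = np.ones((len(counts.samples), 1))
    n = counts.totals.to_numpy(float)
    df = X_full.shape[1] - 1
    n_obs = len(counts.samples)
    contrast_df = n_obs - X_full.shape[1]
    se_inflation = np.sqrt(n_obs / contrast_df)

    rows = []
    for cluster, y in counts.counts.iterrows():
        ya = y.to_numpy(float)
        full = fit_binomial_glmm(ya, n, X_full)
        null = fit_binomial_glmm(ya, n, X_null)
        if full["converged"] and null["converged"]:
            lrt = max(2.0 * (full["loglik"] - null["loglik"]), 0.0)
            p = float(stats.chi2.sf(lrt, df=df))
        else:
            lrt, p = np.nan, np.nan
        row = {"cluster": cluster, "lrt": lrt, "p": p,
               "unstable": not (full["converged"] and null["converged"])}
        # pairwise Wald contrasts from the full fit (reference = order[0])
        if full["converged"]:
            beta = np.concatenate([[0.0], full["beta"][1:]])
            C = np.zeros((X_full.shape[1], X_full.shape[1]))
            C[1:, 1:] = full["cov"][1:, 1:]
            for i in range(len(order)):
                for j in range(i + 1, len(order)):
                    eff = beta[j] - beta[i]
                    var = C[j, j] + C[i, i] - 2 * C[i, j]
                    se = np.sqrt(var) * se_inflation if var > 0 else np.nan
                    zp = (
                        2.0 * stats.t.sf(abs(eff / se), contrast_df)
                        if se and np.isfinite(se)
                        else np.nan
                    )
                    row[f"effect_{order[j]}_vs_{order[i]}"] = eff
                    row[f"p_{order[j]}_vs_{order[i]}"] = zp
        rows.append(row)
    table = pd.DataFrame(rows)
    table["p_adj"], flags = adjust_bh(table["p"].to_numpy(), level=fdr)
    table["significant"] = flags
    return ClusterDAResult(table=table, fdr_level=fdr, p_threshold=1.0)


# ---------------------------------------------------------------------------
# discriminating markers
# ---------------------------------------------------------------------------

def discriminating_markers(
    expr: pd.DataFrame,
    cluster_labels: np.ndarray,
    cluster,
    n_subsample: int = 256,
    seed: int = 0,
    epsilon: float = 0.05,
    cutoff: float = 1.0,
) -> pd.DataFrame:
    """Rank markers by standardized median difference of one cluster vs rest.

    min(n_subsample, size) events are drawn without replacement from every
    cluster (seeded); difference = (median in cluster - median in rest) /
    (pooled MAD + epsilon). Markers with |difference| >= ``cutoff`` carry
    the ``discriminating`` flag.
    """
    labels = np.asarray(cluster_labels)
    in_cluster = labels == cluster
    if not in_cluster.any():
        raise ValidationError(f"cluster {cluster!r} is empty")
    rng = np.random.default_rng(seed)

    def _draw(idx: np.ndarray) -> np.ndarray:
        if idx.size <= n_subsample:
            return idx
        return rng.choice(idx, size=n_subsample, replace=False)

    take_in = _draw(np.flatnonzero(in_cluster))
    take_out_parts = [
        _draw(np.flatnonzero(labels == c)) for c in pd.unique(labels) if c != cluster
    ]
    take_out = (
        np.concatenate(take_out_parts) if take_out_parts else np.array([], dtype=int)
    )
    if take_out.size == 0:
        raise ValidationError("no events outside the cluster to compare against")

    rows = []
    for marker in expr.columns:
        x_in = expr[marker].to_numpy()[take_in]
        x_out = expr[marker].to_numpy()[take_out]
        med_in, med_out = float(np.median(x_in)), float(np.median(x_out))
        mad_pool = float(
            np.median(
                np.concatenate([np.abs(x_in - med_in), np.abs(x_out - med_out)])
            )
        )
        d = (med_in - med_out) / (mad_pool + epsilon)
        rows.append(
            {
                "marker": marker,
                "median_in_cluster": med_in,
                "median_in_rest": med_out,
                "standardized_difference": d,
            }
        )
    out = pd.DataFrame(rows)
    out["rank"] = (
        out["standardized_difference"].abs().rank(ascending=False, method="first")
    ).astype(int)
    out["discriminating"] = out["standardized_difference"].abs() >= cutoff
    return out.sort_values("rank").reset_index(drop=True)
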