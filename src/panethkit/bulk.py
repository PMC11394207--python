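"""Region-wise bulk differential expression and profile grouping.

The DE test is a self-contained negative-binomial Wald test in the
median-of-ratios / NB-GLM tradition: library sizes are normalized with
median-of-ratios size factors, per-gene dispersion comes from a
within-group moment estimate, group means are the closed-form NB-GLM
estimates on normalized counts, and the Wald statistic divides the log2
fold change by its Fisher-information standard error.  It deliberately
omits dispersion shrinkage toward a trend, independent filtering and LFC
shrinkage, so every number is reproducible from the formulas in this file.

Differentially expressed genes (union over pairwise region contrasts at 5%
FDR) are grouped by k-means on per-gene regional expression profiles;
candidate k (2..15) is screened with within-cluster dispersion (elbow),
mean silhouette, and the gap statistic, and the selection rule can take
either the global silhouette optimum or the n-th ranked local optimum
(the finer-granularity rule that picks k = 7 when the global optimum sits
at the number of regions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .core import ConfigError, CountMatrix, PipelineConfig, ValidationError

__all__ = [
    "ProfileGrouping",
    "size_factors",
    "nb_wald_test",
    "deg_union",
    "kmeans_profile_grouping",
    "select_k",
]

ALPHA_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors over genes nonzero in every sample."""
    X = m.to_dense()  # genes x samples
    qualifying = (X > 0).all(axis=1)
    if not qualifying.any():
        raise ValidationError(
            "no gene has nonzero counts in all samples; cannot compute "
            "size factors")
    Xq = X[qualifying]
    log_geomean = np.log(Xq).mean(axis=1)
    ratios = np.log(Xq) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=m.col_ids, name="size_factor")


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------


def _dispersion_trend_floor(base_mean: np.ndarray, alpha: np.ndarray,
                            n_bins: int = 20,
                            min_bin_size: int = 10) -> np.ndarray:
    """Median dispersion per base-mean quantile bin, as a per-gene floor."""
    n = base_mean.size
    if n < 2 * min_bin_size:
        return np.full(n, np.median(alpha))
    n_bins = min(n_bins, n // min_bin_size)
    order = np.argsort(base_mean, kind="stable")
    floor = np.empty(n)
    for chunk in np.array_split(order, n_bins):
        floor[chunk] = np.median(alpha[chunk])
    return floor


def nb_wald_test(
    m: CountMatrix,
    group_a,
    group_b,
    cfg: PipelineConfig | None = None,
    alpha_floor: float = ALPHA_FLOOR,
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test on a genes x samples matrix.

    ``log2FC`` is log2(mean_b / mean_a) on size-factor-normalized counts.
    The standard error follows from the NB Fisher information with the
    moment dispersion estimate; p-values are two-sided normal and q-values
    BH-adjusted.  Genes all-zero in both groups are excluded (reported via
    the ``tested`` flag being absent from the output index).
    """
    cfg = cfg or PipelineConfig()
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("need >= 2 samples per group")
    sf = size_factors(m)
    X = m.to_dense()
    cols_a = m.col_index(group_a)
    cols_b = m.col_index(group_b)
    sa = sf.to_numpy()[cols_a]
    sb = sf.to_numpy()[cols_b]
    Ya = X[:, cols_a] / sa          # normalized counts
    Yb = X[:, cols_b] / sb
    na, nb = len(cols_a), len(cols_b)

    keep = (X[:, cols_a].sum(axis=1) + X[:, cols_b].sum(axis=1)) > 0
    genes = [g for g, k in zip(m.row_ids, keep) if k]
    Ya, Yb = Ya[keep], Yb[keep]

    mean_a = Ya.mean(axis=1)
    mean_b = Yb.mean(axis=1)
    base_mean = np.concatenate([Ya, Yb], axis=1).mean(axis=1)

    # moment dispersion from pooled within-group variance of normalized counts
    resid_ss = (((Ya - mean_a[:, None]) ** 2).sum(axis=1)
                + ((Yb - mean_b[:, None]) ** 2).sum(axis=1))
    df = na + nb - 2
    s2 = resid_ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - base_mean) / base_mean ** 2
    alpha = np.where(np.isfinite(alpha), alpha, alpha_floor)
    alpha = np.maximum(alpha, alpha_floor)
    # The per-gene moment estimate is very noisy at few replicates and
    # underestimates dispersion for about half the genes, which inflates
    # the Wald statistic.  Floor it at a mean-binned median trend: genes
    # are never pulled below the typical dispersion of similarly expressed
    # genes (a floor, not shrinkage; large estimates are kept).
    alpha = np.maximum(alpha, _dispersion_trend_floor(base_mean, alpha))

    # half-count floor keeps log fold changes finite when a group is all-zero
    floor_a = 0.5 / (na * sa.mean())
    floor_b = 0.5 / (nb * sb.mean())
    mu_a = np.maximum(mean_a, floor_a)
    mu_b = np.maximum(mean_b, floor_b)
    log2fc = np.log2(mu_b) - np.log2(mu_a)

    # Var(log mu_hat) from NB sampling noise of the normalized counts:
    # Var(k_j / s_j) = mu / s_j + alpha mu^2, so
    # Var(log mu_hat) = sum_j(1/s_j) / (n^2 mu) + alpha / n
    var_log_a = (1.0 / sa).sum() / (na ** 2) / mu_a + alpha / na
    var_log_b = (1.0 / sb).sum() / (nb ** 2) / mu_b + alpha / nb
    se = np.sqrt(var_log_a + var_log_b) / np.log(2.0)

    wald = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    q = multipletests(p, method="fdr_bh")[1]
    fdr = cfg.de_fdr
    return pd.DataFrame({
        "base_mean": base_mean,
        "log2FC": log2fc,
        "SE": se,
        "wald_stat": wald,
        "p": p,
        "q": q,
        "significant": q < fdr,
    }, index=pd.Index(genes, name="gene"))


def deg_union(results) -> set[str]:
    """Union of significant genes across pairwise DE results."""
    out: set[str] = set()
    for res in results:
        out |= set(res.index[res["significant"]])
    return out


# ---------------------------------------------------------------------------
# K-means profile grouping
# ---------------------------------------------------------------------------


@dataclass
class ProfileGrouping:
    """Per-gene group labels plus per-k diagnostics."""

    genes: list[str]
    labels: np.ndarray               # group ids 1..k for the chosen k
    k: int
    centroids: np.ndarray            # k x n_profile_dims
    profiles: pd.DataFrame           # gene x profile-dimension z-scaled input
    diagnostics: pd.DataFrame        # index k: within_ss, silhouette, gap, gap_se
    assignments: dict[int, np.ndarray]  # k -> labels (1..k) for every screened k

    def members(self, group: int) -> list[str]:
        return [g for g, l in zip(self.genes, self.labels) if l == group]


def _gene_profiles(m: CountMatrix, degs, sample_regions: pd.Series,
                   profile_by: str = "region") -> pd.DataFrame:
    """Per-gene expression profile: log1p of CPM-normalized counts averaged
    per region (or kept per sample), z-scaled per gene."""
    X = m.to_dense()
    depth = X.sum(axis=0)
    logn = np.log1p(X / depth * 1e6)
    df = pd.DataFrame(logn, index=m.row_ids, columns=m.col_ids)
    degs = [g for g in m.row_ids if g in set(degs)]
    df = df.loc[degs]
    if profile_by == "region":
        df = df.T.groupby(sample_regions.reindex(df.columns)).mean().T
        # preserve the proximal-distal column order when recognizable
        order = [r for r in ("duodenum", "jejunum", "ileum") if r in df.columns]
        if order:
            df = df[order + [c for c in df.columns if c not in order]]
    vals = df.to_numpy()
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((vals - mu) / sd, index=df.index, columns=df.columns)


def _gap_statistic(X: np.ndarray, k_values, n_refs: int, n_restarts: int,
                   rng: np.random.Generator,
                   within_ss: dict[int, float]) -> tuple[dict, dict]:
    """Gap(k) = mean_b log W*_kb - log W_k with uniform references drawn in
    the PCA-aligned bounding box of the data."""
    mu = X.mean(axis=0)
    Xc = X - mu
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    proj = Xc @ Vt.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    log_w_refs = {k: [] for k in k_values}
    for _ in range(n_refs):
        ref = rng.uniform(lo, hi, size=proj.shape) @ Vt + mu
        for k in k_values:
            km = KMeans(n_clusters=k, n_init=n_restarts,
                        random_state=int(rng.integers(2 ** 31))).fit(ref)
            log_w_refs[k].append(np.log(km.inertia_))
    gap, gap_se = {}, {}
    for k in k_values:
        logs = np.asarray(log_w_refs[k])
        gap[k] = logs.mean() - np.log(within_ss[k])
        gap_se[k] = logs.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_refs)
    return gap, gap_se


def kmeans_profile_grouping(
    m: CountMatrix,
    degs,
    sample_regions: pd.Series,
    cfg: PipelineConfig | None = None,
    k_chosen: int | None = None,
    n_restarts: int = 10,
    n_gap_refs: int = 50,
    seed: int = 0,
    profile_by: str = "region",
) -> ProfileGrouping:
    """K-means over z-scaled regional expression profiles of the DEGs.

    Screens every k in the configured range, recording within-cluster sum
    of squares, mean silhouette (Euclidean) and the gap statistic (uniform
    references in the PCA-aligned bounding box, Tibshirani's recipe).
    ``k_chosen`` defaults to the configured k = 7.
    """
    cfg = cfg or PipelineConfig()
    degs = list(degs)
    k_values = list(cfg.k_range)
    if max(k_values) >= len(degs):
        raise ConfigError(
            f"k range max ({max(k_values)}) must be < number of DEGs "
            f"({len(degs)})")
    profiles = _gene_profiles(m, degs, sample_regions, profile_by)
    X = profiles.to_numpy()
    rng = np.random.default_rng(seed)

    within_ss: dict[int, float] = {}
    silhouettes: dict[int, float] = {}
    assignments: dict[int, np.ndarray] = {}
    centroids: dict[int, np.ndarray] = {}
    # k = 1 anchors the elbow curve and the gap baseline
    within_ss[1] = float(((X - X.mean(axis=0)) ** 2).sum())
    silhouettes[1] = np.nan
    for k in k_values:
        km = KMeans(n_clusters=k, n_init=n_restarts,
                    random_state=int(rng.integers(2 ** 31))).fit(X)
        within_ss[k] = float(km.inertia_)
        silhouettes[k] = float(silhouette_score(X, km.labels_,
                                                metric="euclidean"))
        assignments[k] = km.labels_ + 1
        centroids[k] = km.cluster_centers_
    gap, gap_se = _gap_statistic(X, [1] + k_values, n_gap_refs, n_restarts,
                                 rng, within_ss)
    diag = pd.DataFrame({
        "within_ss": pd.Series(within_ss),
        "silhouette": pd.Series(silhouettes),
        "gap": pd.Series(gap),
        "gap_se": pd.Series(gap_se),
    }).sort_index()
    diag.index.name = "k"

    k_final = k_chosen or cfg.kmeans_k_chosen
    if k_final not in assignments:
        raise ConfigError(f"chosen k={k_final} outside screened range")
    return ProfileGrouping(
        genes=list(profiles.index),
        labels=assignments[k_final],
        k=k_final,
        centroids=centroids[k_final],
        profiles=profiles,
        diagnostics=diag,
        assignments=assignments,
    )


def select_k(diagnostics: pd.DataFrame, rule: str = "global_optimum",
             n: int = 2) -> int:
    """Pick k from the silhouette curve.

    Local optima of mean silhouette over the screened k grid (ties broken
    by gap statistic, then smaller k) are ranked by silhouette value.
    ``global_optimum`` returns the top-ranked; ``nth_local_optimum``
    returns the n-th ranked (the finer-granularity rule).
    """
    sil = diagnostics["silhouette"].dropna().sort_index()
    ks = sil.index.to_numpy()
    vals = sil.to_numpy()
    if ks.size == 0:
        raise ValidationError("no silhouette diagnostics available")
    gap = diagnostics["gap"].reindex(ks).to_numpy()

    local = []
    for i, k in enumerate(ks):
        left_ok = i == 0 or vals[i] >= vals[i - 1]
        right_ok = i == len(ks) - 1 or vals[i] >= vals[i + 1]
        if left_ok and right_ok:
            local.append(i)
    # collapse plateaus: keep the smallest k of any run of equal neighbors
    pruned = []
    for i in local:
        if pruned and vals[i] == vals[pruned[-1]] and ks[i] == ks[pruned[-1]] + 1:
            continue
        pruned.append(i)
    ranked = sorted(pruned, key=lambda i: (-vals[i], -gap[i], ks[i]))

    if rule == "global_optimum":
        return int(ks[ranked[0]])
    if rule == "nth_local_optimum":
        if n > len(ranked):
            avail = [int(ks[i]) for i in ranked]
            raise ValidationError(
                f"requested local optimum #{n} but only {len(ranked)} "
                f"exist (at k = {avail})")
        return int(ks[ranked[n - 1]])
    raise ConfigError(f"unknown rule {rule!r}")
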