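"""Linking single-cell clusters to intestinal regions.

Single-cell counts are aggregated to cluster-level pseudo-bulk profiles;
those profiles are compared with the regional bulk samples by correlation
on log1p counts-per-million over a differential-gene set, and regional
mixture weights are recovered by non-negative least squares.  A margin
rule converts each cluster's correlation row into a region assignment
(single region, joint label for adjacent regions along the
duodenum-jejunum-ileum axis, or 'uniform').
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
from scipy import stats

from .core import CountMatrix, ValidationError
from .sc import ClusterLabeling

__all__ = [
    "PseudoBulk",
    "ClusterRegionMap",
    "pseudobulk",
    "correlate_clusters_regions",
    "fit_region_mixture",
    "assign_regions",
]

REGION_ORDER = ("duodenum", "jejunum", "ileum")
AGGREGATE_ID = "__all__"


@dataclass
class PseudoBulk:
    """Cluster x gene aggregated counts plus the all-cells aggregate."""

    counts: pd.DataFrame           # index: cluster ids as str + AGGREGATE_ID
    cell_counts: pd.Series        # cells per cluster

    @property
    def cluster_ids(self) -> list[str]:
        return [i for i in self.counts.index if i != AGGREGATE_ID]

    def log1p_cpm(self) -> pd.DataFrame:
        depth = self.counts.sum(axis=1)
        return np.log1p(self.counts.div(depth, axis=0) * 1e6)


@dataclass
class ClusterRegionMap:
    correlations: pd.DataFrame     # cluster x region
    assignments: pd.Series         # cluster -> region label
    mixture_weights: pd.DataFrame | None = None  # region x cluster


def pseudobulk(m: CountMatrix, labeling: ClusterLabeling) -> PseudoBulk:
    """Aggregate raw counts per cluster; add the all-cells aggregate row.

    The sum over clusters of every gene equals the aggregate row exactly
    (integer conservation).
    """
    if m.layer_tag != "raw_counts":
        raise ValidationError("pseudobulk requires raw counts")
    if list(labeling.cell_ids) != list(m.row_ids):
        lookup = dict(zip(labeling.cell_ids, labeling.labels))
        missing = [c for c in m.row_ids if c not in lookup]
        if missing:
            raise ValidationError(
                f"{len(missing)} cells of the matrix are unlabeled "
                f"(first: {missing[0]!r})")
        labels = np.array([lookup[c] for c in m.row_ids])
    else:
        labels = labeling.labels
    X = m.values if sp.issparse(m.values) else sp.csr_matrix(m.values)
    clusters = np.unique(labels)
    rows = {}
    for c in clusters:
        idx = np.flatnonzero(labels == c)
        rows[str(c)] = np.asarray(X[idx].sum(axis=0)).ravel()
    df = pd.DataFrame(rows, index=m.col_ids).T
    df.loc[AGGREGATE_ID] = df.sum(axis=0)
    df = df.astype(np.int64)
    cell_counts = pd.Series({str(c): int((labels == c).sum()) for c in clusters})
    return PseudoBulk(df, cell_counts)


def _bulk_log1p_cpm(bulk: CountMatrix) -> pd.DataFrame:
    X = bulk.to_dense()  # genes x samples
    depth = X.sum(axis=0)
    return pd.DataFrame(np.log1p(X / depth * 1e6), index=bulk.row_ids,
                        columns=bulk.col_ids)


def _intersect_genes(pb: PseudoBulk, bulk: CountMatrix, gene_set) -> list[str]:
    shared = set(pb.counts.columns) & set(bulk.row_ids)
    genes = [g for g in bulk.row_ids if g in shared and g in set(gene_set)]
    if len(genes) < 3:
        raise ValidationError(
            f"only {len(genes)} shared genes after intersection; need >= 3")
    if len(genes) < 10:
        import warnings
        warnings.warn(f"only {len(genes)} genes in the intersection",
                      stacklevel=3)
    return genes


def correlate_clusters_regions(
    pb: PseudoBulk,
    bulk: CountMatrix,
    gene_set,
    sample_regions: pd.Series,
    method: str = "pearson",
) -> pd.DataFrame:
    """Cluster x region correlation matrix on log1p CPM.

    Bulk samples are averaged per region after the transform; the
    correlation is computed over the intersection of ``gene_set`` with the
    genes shared between pseudo-bulk and bulk.
    """
    genes = _intersect_genes(pb, bulk, gene_set)
    pb_prof = pb.log1p_cpm().loc[pb.cluster_ids, genes]
    bulk_prof = _bulk_log1p_cpm(bulk).loc[genes]
    region_prof = bulk_prof.T.groupby(
        sample_regions.reindex(bulk_prof.columns)).mean()
    regions = [r for r in REGION_ORDER if r in region_prof.index] \
        + [r for r in region_prof.index if r not in REGION_ORDER]
    out = pd.DataFrame(index=pb_prof.index, columns=regions, dtype=float)
    for r in regions:
        y = region_prof.loc[r].to_numpy()
        for c in pb_prof.index:
            x = pb_prof.loc[c].to_numpy()
            if method == "pearson":
                out.loc[c, r] = stats.pearsonr(x, y)[0]
            elif method == "spearman":
                out.loc[c, r] = stats.spearmanr(x, y)[0]
            else:
                raise ValidationError(f"unknown method {method!r}")
    out.index.name = "cluster"
    return out


def fit_region_mixture(
    pb: PseudoBulk,
    bulk_sample: pd.Series,
    gene_set,
) -> tuple[pd.Series, float]:
    """NNLS mixture weights of cluster profiles for one bulk sample.

    Regresses the sample's log1p-CPM vector on the cluster log1p-CPM
    profiles over ``gene_set`` with non-negativity; weights are normalized
    to sum to one.  Returns (weights, residual norm).
    """
    cluster_ids = pb.cluster_ids
    if len(cluster_ids) < 2:
        raise ValidationError("need >= 2 clusters")
    shared = [g for g in bulk_sample.index
              if g in set(gene_set) and g in set(pb.counts.columns)]
    if len(shared) < 3:
        raise ValidationError("fewer than 3 usable genes for the regression")
    A = pb.log1p_cpm().loc[cluster_ids, shared].to_numpy().T
    if np.allclose(A - A.mean(axis=1, keepdims=True), 0.0):
        raise ValidationError(
            "cluster profiles are collinear (all identical); mixture is "
            "unidentifiable")
    depth = bulk_sample.sum()
    y = np.log1p(bulk_sample.loc[shared].to_numpy() / depth * 1e6)
    w, residual = scipy.optimize.nnls(A, y)
    total = w.sum()
    if total == 0:
        raise ValidationError("NNLS returned the zero solution")
    return pd.Series(w / total, index=cluster_ids, name="weight"), float(residual)


def assign_regions(corr: pd.DataFrame, margin: float = 0.05,
                   mixture_weights: pd.DataFrame | None = None) -> ClusterRegionMap:
    """Margin rule on each cluster's correlation row.

    Regions within ``margin`` of the row maximum form the assignment:
    one region gives that label; two adjacent regions give a joint label
    (e.g. 'jejunum/ileum'); a non-adjacent pair or all three give
    'uniform'.
    """
    vals = corr.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValidationError("correlation matrix contains non-finite values")
    regions = list(corr.columns)
    order = {r: i for i, r in enumerate(REGION_ORDER) if r in regions}
    assignments = {}
    for cluster, row in corr.iterrows():
        top = row.max()
        winners = [r for r in regions if row[r] >= top - margin]
        if len(winners) == 1:
            label = winners[0]
        elif len(winners) == 2 and all(w in order for w in winners) \
                and abs(order[winners[0]] - order[winners[1]]) == 1:
            winners = sorted(winners, key=lambda r: order[r])
            label = f"{winners[0]}/{winners[1]}"
        else:
            label = "uniform"
        assignments[cluster] = label
    return ClusterRegionMap(
        correlations=corr,
        assignments=pd.Series(assignments, name="region"),
        mixture_weights=mixture_weights,
    )
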