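"""Single-cell processing: QC, normalization, variable genes, cell-cycle
regression, PCA (with jackstraw PC selection), SNN + Leiden clustering,
marker detection and signature-based cluster annotation.

The stages mirror a standard droplet scRNA-seq workflow for sorted Paneth
cells: genes kept when detected in >= 10 cells; cells kept with 100-2500
detected features and <= 5% mitochondrial counts; log-normalization to a
10,000-count library; 2,000 variable genes; cell-cycle scores regressed out
of the scaled data; 15 principal components feeding a shared-nearest-
neighbor graph clustered with Leiden; markers gated on 60% detection and a
10% detection-fraction difference, tested with a two-sided Wilcoxon
rank-sum (exact by enumeration for small groups) and BH-corrected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .core import (
    ConfigError,
    CountMatrix,
    EmptyResultError,
    PipelineConfig,
    ValidationError,
)

__all__ = [
    "CellQCReport",
    "ClusterLabeling",
    "ScPipelineResult",
    "qc_filter",
    "lognormalize",
    "select_variable_genes",
    "scale_matrix",
    "score_and_regress_cell_cycle",
    "run_pca",
    "jackstraw_select_pcs",
    "cluster_cells",
    "find_markers",
    "annotate_clusters",
    "flag_doublets",
    "run_sc_pipeline",
    "wilcoxon_rank_sum",
]

ANNOTATION_LABELS = ("mature_PC", "TC_PC", "GC_PC", "immature_PC",
                     "mito_high", "mito_low", "unassigned")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class CellQCReport:
    """Per-cell QC metrics and the removal ledger of :func:`qc_filter`."""

    per_cell: pd.DataFrame           # total_counts, n_features, mito_fraction, flags
    n_genes_in: int
    n_genes_removed: int
    n_cells_in: int
    n_cells_removed_features: int
    n_cells_removed_mito: int

    @property
    def n_cells_out(self) -> int:
        return (self.n_cells_in - self.n_cells_removed_features
                - self.n_cells_removed_mito)


@dataclass
class ClusterLabeling:
    """Per-cell integer cluster labels with optional per-cluster annotation."""

    cell_ids: list[str]
    labels: np.ndarray
    annotation: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.cell_ids) != self.labels.size:
            raise ValidationError("cell_ids and labels length mismatch")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()

    def annotated(self) -> pd.Series:
        ann = self.annotation or {}
        return pd.Series(
            [ann.get(int(l), "unassigned") for l in self.labels],
            index=self.cell_ids, name="annotation")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cell": self.cell_ids, "cluster": self.labels})
        if self.annotation is not None:
            df["annotation"] = self.annotated().to_numpy()
        return df


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def _mito_gene_mask(m: CountMatrix, mito_genes, prefix: str) -> np.ndarray:
    if mito_genes is not None:
        mset = set(mito_genes)
        return np.array([g in mset for g in m.col_ids])
    return np.array([g.startswith(prefix) for g in m.col_ids])


def qc_filter(m: CountMatrix, cfg: PipelineConfig,
              mito_genes=None) -> tuple[CountMatrix, CellQCReport]:
    """Three-stage QC: gene detection, per-cell feature bounds, mito cut-off.

    Genes detected in fewer than ``cfg.sc_min_cells`` cells are removed
    first; then cells with a feature count outside
    [``sc_min_features``, ``sc_max_features``]; finally cells whose
    mitochondrial fraction exceeds ``sc_max_mito_fraction``.  Metrics in the
    report are computed on the gene-filtered matrix.
    """
    if m.layer_tag != "raw_counts":
        raise ValidationError("qc_filter requires the raw_counts layer")
    X = m.values if sp.issparse(m.values) else sp.csr_matrix(m.values)
    n_cells, n_genes = X.shape

    detected_cells = np.asarray((X > 0).sum(axis=0)).ravel()
    gene_keep = detected_cells >= cfg.sc_min_cells
    Xg = X[:, np.flatnonzero(gene_keep)]
    kept_gene_ids = [g for g, k in zip(m.col_ids, gene_keep) if k]

    total = np.asarray(Xg.sum(axis=1)).ravel()
    n_feat = np.asarray((Xg > 0).sum(axis=1)).ravel()
    mito_mask = _mito_gene_mask(
        CountMatrix(Xg, m.row_ids, kept_gene_ids, "raw_counts", validate=False),
        mito_genes, cfg.mito_prefix)
    mito_counts = np.asarray(Xg[:, np.flatnonzero(mito_mask)].sum(axis=1)).ravel() \
        if mito_mask.any() else np.zeros(n_cells)
    mito_frac = np.divide(mito_counts, total, out=np.zeros_like(mito_counts,
                          dtype=float), where=total > 0)

    pass_features = ((n_feat >= cfg.sc_min_features)
                     & (n_feat <= cfg.sc_max_features))
    pass_mito = mito_frac <= cfg.sc_max_mito_fraction
    cell_keep = pass_features & pass_mito

    report = CellQCReport(
        per_cell=pd.DataFrame({
            "total_counts": total,
            "n_features": n_feat,
            "mito_fraction": mito_frac,
            "pass_features": pass_features,
            "pass_mito": pass_mito,
            "kept": cell_keep,
        }, index=m.row_ids),
        n_genes_in=n_genes,
        n_genes_removed=int((~gene_keep).sum()),
        n_cells_in=n_cells,
        n_cells_removed_features=int((~pass_features).sum()),
        n_cells_removed_mito=int((pass_features & ~pass_mito).sum()),
    )
    if not cell_keep.any() or not gene_keep.any():
        raise EmptyResultError("QC filtering removed all cells or all genes")
    kept_cell_ids = [c for c, k in zip(m.row_ids, cell_keep) if k]
    out = CountMatrix(Xg[np.flatnonzero(cell_keep), :], kept_cell_ids,
                      kept_gene_ids, "raw_counts", validate=False)
    return out, report


# ---------------------------------------------------------------------------
# Normalization and scaling
# ---------------------------------------------------------------------------


def lognormalize(m: CountMatrix, scale_total: float = 10000.0) -> CountMatrix:
    """value' = ln(1 + scale_total * x / cell_total), per cell."""
    if m.layer_tag != "raw_counts":
        raise ValidationError("lognormalize requires the raw_counts layer")
    if sp.issparse(m.values):
        total = np.asarray(m.values.sum(axis=1)).ravel()
    else:
        total = m.values.sum(axis=1)
    if (total <= 0).any():
        raise ValidationError(
            "cells with zero total counts present; run qc_filter first")
    if sp.issparse(m.values):
        out = m.values.astype(float).tocsr(copy=True)
        scale = scale_total / total
        out.data *= np.repeat(scale, np.diff(out.indptr))
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(m.values * (scale_total / total)[:, None])
    return CountMatrix(out, m.row_ids, m.col_ids, "lognorm", validate=False)


def select_variable_genes(m: CountMatrix, n: int = 2000) -> list[str]:
    """Rank genes by variance of clipped standardized raw counts.

    A quadratic mean-variance trend is fitted in log10 space; counts are
    standardized per gene with the trend's expected standard deviation,
    clipped at sqrt(n_cells), and the genes with the highest clipped
    variance are returned (deterministic; ties broken by gene order).
    """
    if n <= 0:
        raise ConfigError("n must be positive")
    if m.layer_tag != "raw_counts":
        raise ValidationError("select_variable_genes requires raw counts")
    X = m.to_dense()
    n_cells, n_genes = X.shape
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if n_cells > 1 else np.zeros(n_genes)
    fit_mask = (mean > 0) & (var > 0)
    if fit_mask.sum() >= 3:
        lm, lv = np.log10(mean[fit_mask]), np.log10(var[fit_mask])
        coef = np.polyfit(lm, lv, deg=2)
        expected_var = np.zeros(n_genes)
        expected_var[fit_mask] = 10 ** np.polyval(coef, lm)
    else:  # degenerate fixture: fall back to the raw variance
        expected_var = np.where(var > 0, var, 1.0)
    sd = np.sqrt(np.where(expected_var > 0, expected_var, 1.0))
    clip = math.sqrt(n_cells)
    Z = np.clip((X - mean) / sd, -clip, clip)
    score = Z.var(axis=0, ddof=1) if n_cells > 1 else np.zeros(n_genes)
    score[~fit_mask] = -np.inf  # constant genes never outrank varying ones
    order = np.lexsort((np.arange(n_genes), -score))
    return [m.col_ids[i] for i in order[: min(n, n_genes)]]


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def scale_matrix(m: CountMatrix, clip: float = 10.0) -> CountMatrix:
    """Per-gene z-score of the lognorm layer, clipped at +-clip."""
    if m.layer_tag != "lognorm":
        raise ValidationError("scale_matrix requires the lognorm layer")
    Z = np.clip(_zscore(m.to_dense()), -clip, clip)
    return CountMatrix(Z, m.row_ids, m.col_ids, "scaled", validate=False)


def score_and_regress_cell_cycle(
    m: CountMatrix,
    s_genes,
    g2m_genes,
    clip: float = 10.0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Score S/G2M programs and regress them out of the scaled matrix.

    Phase scores are the mean per-gene z-score over each gene set (absent
    genes are dropped with a warning).  Every gene's z-scored values are
    replaced by the residuals of an OLS fit on the available scores, then
    re-standardized per gene and clipped.
    """
    if m.layer_tag != "lognorm":
        raise ValidationError("requires the lognorm layer")
    gene_pos = {g: i for i, g in enumerate(m.col_ids)}
    s_present = [g for g in s_genes if g in gene_pos]
    g2m_present = [g for g in g2m_genes if g in gene_pos]
    for name, requested, present in (("S", list(s_genes), s_present),
                                     ("G2M", list(g2m_genes), g2m_present)):
        if requested and len(present) < len(requested):
            warnings.warn(
                f"{len(requested) - len(present)} {name}-phase genes absent "
                "from the matrix", stacklevel=2)
    if not s_present and not g2m_present:
        raise ValidationError("no cell-cycle gene present in the matrix")

    Z = _zscore(m.to_dense())
    scores = {}
    covariates = []
    if s_present:
        scores["S"] = Z[:, [gene_pos[g] for g in s_present]].mean(axis=1)
        covariates.append(scores["S"])
    if g2m_present:
        scores["G2M"] = Z[:, [gene_pos[g] for g in g2m_present]].mean(axis=1)
        covariates.append(scores["G2M"])
    score_df = pd.DataFrame(scores, index=m.row_ids)

    X = np.column_stack([np.ones(Z.shape[0])] + covariates)
    beta, *_ = np.linalg.lstsq(X, Z, rcond=None)
    resid = Z - X @ beta
    out = np.clip(_zscore(resid), -clip, clip)
    return CountMatrix(out, m.row_ids, m.col_ids, "scaled",
                       validate=False), score_df


# ---------------------------------------------------------------------------
# PCA and jackstraw
# ---------------------------------------------------------------------------


def run_pca(m: CountMatrix, n_pcs: int = 15) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic full-SVD PCA on the scaled layer.

    Returns the cells x n_pcs embedding and the explained-variance ratios
    (non-increasing).  Deterministic up to overall component sign.
    """
    if m.layer_tag != "scaled":
        raise ValidationError("run_pca requires the scaled layer")
    X = m.to_dense()
    if n_pcs >= min(X.shape):
        raise ConfigError(
            f"n_pcs={n_pcs} must be < min(n_cells, n_genes)={min(X.shape)}")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    emb = pca.fit_transform(X)
    return emb, pca.explained_variance_ratio_


def jackstraw_select_pcs(
    m: CountMatrix,
    n_pcs: int = 15,
    n_perm: int = 100,
    frac_genes: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[int]:
    """Permutation test for principal-component significance.

    Each round permutes a random ``frac_genes`` of genes across cells,
    recomputes the PCA and pools the permuted genes' absolute loadings as a
    null per PC.  A PC is significant when the observed gene loadings are
    stochastically larger than the null (one-sided rank-sum p < alpha).
    Returns the significant PCs as a 0-based prefix: the first
    non-significant PC truncates the list.
    """
    if not 0.0 < frac_genes <= 0.5:
        raise ConfigError("frac_genes must be in (0, 0.5]")
    if n_perm < 20:
        raise ConfigError("n_perm must be >= 20")
    if m.layer_tag != "scaled":
        raise ValidationError("jackstraw requires the scaled layer")
    X = m.to_dense()
    n_cells, n_genes = X.shape
    n_pcs = min(n_pcs, min(X.shape) - 1)
    rng = np.random.default_rng(seed)

    pca = PCA(n_components=n_pcs, svd_solver="full")
    pca.fit(X)
    observed = np.abs(pca.components_)          # n_pcs x n_genes

    n_sub = max(1, int(round(frac_genes * n_genes)))
    null = [[] for _ in range(n_pcs)]
    for _ in range(n_perm):
        Xp = X.copy()
        genes = rng.choice(n_genes, size=n_sub, replace=False)
        for g in genes:
            Xp[:, g] = Xp[rng.permutation(n_cells), g]
        p = PCA(n_components=n_pcs, svd_solver="full").fit(Xp)
        load = np.abs(p.components_[:, genes])
        for pc in range(n_pcs):
            null[pc].append(load[pc])
    significant: list[int] = []
    for pc in range(n_pcs):
        pooled = np.concatenate(null[pc])
        stat = stats.mannwhitneyu(observed[pc], pooled, alternative="greater")
        if stat.pvalue < alpha:
            significant.append(pc)
        else:
            break
    return significant


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_cells(
    embedding: np.ndarray,
    knn_k: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
    prune: float = 1.0 / 15.0,
    cell_ids=None,
) -> ClusterLabeling:
    """SNN-Jaccard graph + Leiden partition on a PC embedding.

    A k-nearest-neighbor graph (self included) is converted to
    shared-nearest-neighbor Jaccard weights; edges below ``prune`` are
    dropped; the Leiden algorithm (RB-configuration quality) partitions the
    graph at the given resolution.  Labels are relabeled by decreasing
    cluster size.
    """
    import igraph
    import leidenalg

    embedding = np.asarray(embedding, dtype=float)
    if not np.isfinite(embedding).all():
        raise ValidationError("embedding contains non-finite values")
    n = embedding.shape[0]
    if knn_k >= n:
        raise ConfigError(f"knn_k={knn_k} must be < n_cells={n}")

    nn = NearestNeighbors(n_neighbors=knn_k).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    rows = np.repeat(np.arange(n), knn_k)
    A = sp.csr_matrix((np.ones(rows.size), (rows, idx.ravel())), shape=(n, n))
    A.data[:] = 1.0
    shared = (A @ A.T).tocoo()                  # |N_i & N_j|
    i, j, inter = shared.row, shared.col, shared.data
    keep = i < j
    i, j, inter = i[keep], j[keep], inter[keep]
    jaccard = inter / (2 * knn_k - inter)
    strong = jaccard >= prune
    edges = np.column_stack((i[strong], j[strong]))
    weights = jaccard[strong]

    g = igraph.Graph(n=n, edges=edges.tolist())
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=list(weights), resolution_parameter=resolution, seed=seed)
    raw = np.asarray(part.membership)
    order = pd.Series(raw).value_counts(sort=True).index.to_numpy()
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(l)] for l in raw])
    if cell_ids is None:
        cell_ids = [str(i) for i in range(n)]
    return ClusterLabeling(list(cell_ids), labels)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 20000  # max number of enumerated group assignments


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p-value; exact by enumeration for small groups.

    The exact path enumerates every assignment of the combined sample into
    groups of the observed sizes and counts assignments whose rank-sum
    deviates from its mean at least as much as observed (midranks for
    ties).  Larger groups use the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be nonempty")
    if math.comb(n1 + n2, n1) <= _EXACT_LIMIT:
        ranks = stats.rankdata(np.concatenate([x, y]))
        obs = ranks[:n1].sum()
        mu = n1 * (n1 + n2 + 1) / 2.0
        dev = abs(obs - mu)
        count = 0
        total = 0
        for comb in combinations(range(n1 + n2), n1):
            total += 1
            w = ranks[list(comb)].sum()
            if abs(w - mu) >= dev - 1e-9:
                count += 1
        return count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------


def find_markers(m: CountMatrix, labeling: ClusterLabeling,
                 cfg: PipelineConfig) -> pd.DataFrame:
    """One-vs-rest marker table under the 60%/10% detection gates.

    Per cluster, only genes with max(pct_in, pct_out) >= ``marker_min_pct``
    and |pct_in - pct_out| >= ``marker_min_diff`` are tested (two-sided
    Wilcoxon rank-sum on log-normalized values).  BH correction is pooled
    over all performed tests.  log2FC compares expm1 means with a +1
    pseudocount; direction is its sign.
    """
    if m.layer_tag != "lognorm":
        raise ValidationError("find_markers requires the lognorm layer")
    labels = labeling.labels
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValidationError("need >= 2 clusters to find markers")
    X = m.to_dense()
    rows = []
    for c in clusters:
        in_mask = labels == c
        if in_mask.sum() < 2:
            warnings.warn(f"cluster {c} is a singleton; skipped", stacklevel=2)
            continue
        Xin, Xout = X[in_mask], X[~in_mask]
        pct_in = (Xin > 0).mean(axis=0)
        pct_out = (Xout > 0).mean(axis=0)
        gate = (np.maximum(pct_in, pct_out) >= cfg.marker_min_pct) \
            & (np.abs(pct_in - pct_out) >= cfg.marker_min_diff)
        mean_in = np.expm1(Xin).mean(axis=0)
        mean_out = np.expm1(Xout).mean(axis=0)
        log2fc = np.log2(mean_in + 1.0) - np.log2(mean_out + 1.0)
        for g in np.flatnonzero(gate):
            p = wilcoxon_rank_sum(Xin[:, g], Xout[:, g])
            rows.append((int(c), m.col_ids[g], float(log2fc[g]),
                         float(pct_in[g]), float(pct_out[g]), p))
    table = pd.DataFrame(rows, columns=["cluster", "gene", "log2FC",
                                        "pct_in", "pct_out", "p"])
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        table["direction"] = np.where(table["log2FC"] >= 0, "up", "down")
    else:
        table["q"] = pd.Series(dtype=float)
        table["direction"] = pd.Series(dtype=str)
    return table


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def annotate_clusters(
    markers: pd.DataFrame,
    m: CountMatrix,
    labeling: ClusterLabeling,
    signatures: dict[str, list[str]],
    mito_genes=None,
    mito_prefix: str = "mt-",
    margin: float = 0.25,
    mito_high_ratio: float = 2.0,
    mito_low_ratio: float = 0.5,
) -> ClusterLabeling:
    """Assign subtype labels to clusters from signature scores.

    Clusters whose mean mitochondrial expression exceeds
    ``mito_high_ratio`` x the cross-cluster median are labeled mito_high
    (symmetrically mito_low below ``mito_low_ratio`` x).  Otherwise the
    argmax signature (mean z-score over the set) wins if it beats the
    runner-up by ``margin``; ties and weak scores fall back to mature_PC.
    """
    if not signatures or all(len(v) == 0 for v in signatures.values()):
        raise ValidationError("signature sets must be nonempty")
    if m.layer_tag != "lognorm":
        raise ValidationError("annotate_clusters requires the lognorm layer")
    gene_pos = {g: i for i, g in enumerate(m.col_ids)}
    present = {name: [gene_pos[g] for g in genes if g in gene_pos]
               for name, genes in signatures.items()}
    if all(len(v) == 0 for v in present.values()):
        raise ValidationError("no signature gene present in the matrix")

    X = m.to_dense()
    Z = _zscore(X)
    labels = labeling.labels
    clusters = np.unique(labels)

    mito_mask = _mito_gene_mask(m, mito_genes, mito_prefix)
    mito_cols = np.flatnonzero(mito_mask)
    mito_score = {}
    for c in clusters:
        cells = labels == c
        if mito_cols.size:
            mito_score[c] = float(np.expm1(X[np.ix_(cells, mito_cols)]).mean())
        else:
            mito_score[c] = 0.0
    med = float(np.median(list(mito_score.values()))) if mito_score else 0.0

    annotation: dict[int, str] = {}
    for c in clusters:
        if mito_cols.size and med > 0:
            if mito_score[c] > mito_high_ratio * med:
                annotation[int(c)] = "mito_high"
                continue
            if mito_score[c] < mito_low_ratio * med:
                annotation[int(c)] = "mito_low"
                continue
        cells = labels == c
        scores = {name: float(Z[np.ix_(cells, cols)].mean())
                  for name, cols in present.items() if cols}
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        if len(ranked) == 1:
            top, top_score = ranked[0]
            runner = -np.inf
        else:
            (top, top_score), (_, runner) = ranked[0], ranked[1]
        if top_score - runner >= margin and top_score > 0:
            annotation[int(c)] = top
        else:
            annotation[int(c)] = "mature_PC"
    return ClusterLabeling(labeling.cell_ids, labels, annotation)


def flag_doublets(
    m: CountMatrix,
    lognorm: CountMatrix,
    signatures: dict[str, list[str]],
    total_percentile: float = 99.5,
    score_threshold: float = 1.0,
) -> np.ndarray:
    """Non-destructive doublet flag.

    A cell is flagged when its total counts exceed the ``total_percentile``
    percentile AND it scores above ``score_threshold`` (mean z) for at
    least two distinct signatures.
    """
    if m.layer_tag != "raw_counts":
        raise ValidationError("flag_doublets requires raw counts")
    total = np.asarray(m.values.sum(axis=1)).ravel()
    cutoff = np.percentile(total, total_percentile)
    Z = _zscore(lognorm.to_dense())
    gene_pos = {g: i for i, g in enumerate(lognorm.col_ids)}
    n_hits = np.zeros(m.shape[0], dtype=int)
    for genes in signatures.values():
        cols = [gene_pos[g] for g in genes if g in gene_pos]
        if cols:
            n_hits += Z[:, cols].mean(axis=1) > score_threshold
    return (total > cutoff) & (n_hits >= 2)


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------


@dataclass
class ScPipelineResult:
    qc_report: CellQCReport
    filtered: CountMatrix
    lognorm: CountMatrix
    variable_genes: list[str]
    scaled: CountMatrix
    cc_scores: pd.DataFrame | None
    embedding: np.ndarray
    explained_variance: np.ndarray
    labeling: ClusterLabeling
    markers: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_sc_pipeline(
    m: CountMatrix,
    cfg: PipelineConfig,
    signatures: dict[str, list[str]] | None = None,
    s_genes=None,
    g2m_genes=None,
    mito_genes=None,
    regress_cycle: bool = True,
    compute_markers: bool = True,
    n_pcs: int | None = None,
) -> ScPipelineResult:
    """QC -> lognorm -> variable genes -> (cell-cycle regression) -> PCA ->
    SNN/Leiden clustering -> markers -> signature annotation."""
    filtered, report = qc_filter(m, cfg, mito_genes=mito_genes)
    logn = lognormalize(filtered, cfg.sc_scale_total)
    hvg = select_variable_genes(filtered, cfg.sc_n_variable)
    logn_hvg = logn.subset(cols=logn.col_index(hvg))
    if regress_cycle and (s_genes or g2m_genes):
        scaled, cc_scores = score_and_regress_cell_cycle(
            logn_hvg, s_genes or [], g2m_genes or [])
    else:
        scaled, cc_scores = scale_matrix(logn_hvg), None
    emb, evr = run_pca(scaled, n_pcs or cfg.sc_n_pcs)
    labeling = cluster_cells(emb, knn_k=cfg.snn_k,
                             resolution=cfg.leiden_resolution,
                             seed=cfg.rng_seed, prune=cfg.snn_prune,
                             cell_ids=filtered.row_ids)
    markers = pd.DataFrame()
    if compute_markers and labeling.n_clusters >= 2:
        markers = find_markers(logn, labeling, cfg)
    if signatures:
        labeling = annotate_clusters(markers, logn, labeling, signatures,
                                     mito_genes=mito_genes,
                                     mito_prefix=cfg.mito_prefix)
    return ScPipelineResult(report, filtered, logn, hvg, scaled, cc_scores,
                            emb, evr, labeling, markers)
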