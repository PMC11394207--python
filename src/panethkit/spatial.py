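"""Cell-based molecular-cartography processing.

The stages mirror an in-house spot-based spatial transcriptomics pipeline:
tile stitching and background subtraction, nuclei segmentation (a built-in
classical segmenter; external label masks are accepted as a pluggable
backend), Voronoi expansion of the nuclei by a fixed radius, assignment of
transcript spots to the expanded territories with retention accounting,
cell-free co-location analysis, replicate merging with a batch-mixing
check, and mapping cluster identities back onto image coordinates.

Voronoi expansion rule: every background pixel within ``radius`` of a
labeled pixel receives the label of the nearest labeled pixel; equidistant
ties go to the smaller label.  Distances are exact Euclidean (integer
squared distances internally, so the tie rule is exact).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy import stats
from scipy.spatial import cKDTree
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed
from statsmodels.stats.multitest import multipletests

from .core import (
    ConfigError,
    CountMatrix,
    FormatError,
    PipelineConfig,
    ValidationError,
    spot_pixels,
)
from .sc import ClusterLabeling, cluster_cells, lognormalize, run_pca, scale_matrix

__all__ = [
    "RetentionReport",
    "BatchMixingReport",
    "preprocess_image",
    "segment_nuclei",
    "expand_labels_voronoi",
    "assign_transcripts",
    "retention_curve",
    "coloc_analysis",
    "merge_replicates",
    "map_clusters_spatial",
    "default_spatial_config",
    "cluster_spatial_cells",
]


def default_spatial_config(**overrides) -> PipelineConfig:
    """QC/clustering defaults for panel-sized (<= ~100 gene) spatial data.

    The scRNA feature thresholds do not transfer to a small targeted
    panel, so the per-cell feature floor drops to 5 and the gene-detection
    floor to 3 cells; 17 PCs are used for clustering.
    """
    defaults = dict(sc_min_cells=3, sc_min_features=5, sc_max_features=10000,
                    sc_max_mito_fraction=1.0, sc_n_pcs=17, snn_k=15)
    defaults.update(overrides)
    return PipelineConfig(**defaults)


# ---------------------------------------------------------------------------
# Image preprocessing
# ---------------------------------------------------------------------------


def preprocess_image(tiles, grid: tuple[int, int] | None = None,
                     background_radius: int = 25,
                     subtract_background: bool = True) -> np.ndarray:
    """Stitch tiles row-major, subtract background, rescale to [0, 1].

    ``tiles`` is either a single 2-D frame or a flat list of equally shaped
    2-D tiles with a ``grid=(rows, cols)`` layout.  Background estimation
    is a rolling-ball-style grayscale opening (min filter then max filter
    with a square window of half-width ``background_radius``).
    """
    if grid is None:
        frame = np.asarray(tiles, dtype=float)
        if frame.ndim != 2:
            raise FormatError("expected a single 2-D frame when grid is None")
    else:
        rows, cols = grid
        tiles = [np.asarray(t, dtype=float) for t in tiles]
        if len(tiles) != rows * cols:
            raise FormatError(f"{len(tiles)} tiles for a {rows}x{cols} grid")
        shapes = {t.shape for t in tiles}
        if len(shapes) != 1 or any(t.ndim != 2 for t in tiles):
            raise FormatError(f"inconsistent tile shapes: {sorted(shapes)}")
        frame = np.block([[tiles[r * cols + c] for c in range(cols)]
                          for r in range(rows)])
    if subtract_background:
        size = 2 * background_radius + 1
        background = ndi.maximum_filter(
            ndi.minimum_filter(frame, size=size), size=size)
        frame = np.clip(frame - background, 0.0, None)
    lo, hi = frame.min(), frame.max()
    if hi > lo:
        frame = (frame - lo) / (hi - lo)
    else:
        frame = np.zeros_like(frame)
    return frame


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def segment_nuclei(img: np.ndarray, diameter_px: float = 30.0) -> np.ndarray:
    """Classical nuclei segmentation at an expected diameter.

    Gaussian smoothing (sigma = diameter/6), Otsu threshold, hole filling,
    removal of objects smaller than 0.2 * pi * (diameter/2)^2, then a
    distance-transform watershed with peak separation >= diameter/2.
    External masks (e.g. from a learned segmenter) can be supplied to the
    downstream steps instead.
    """
    img = np.asarray(img, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValidationError("image must be scaled to [0, 1]")
    if img.max() == img.min():
        warnings.warn("blank image: no nuclei segmented", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32)
    smooth = gaussian(img, sigma=diameter_px / 6.0)
    thresh = threshold_otsu(smooth)
    binary = smooth > thresh
    binary = ndi.binary_fill_holes(binary)
    min_size = int(0.2 * np.pi * (diameter_px / 2.0) ** 2)
    comp, n_comp = ndi.label(binary)
    if n_comp:
        sizes = np.bincount(comp.ravel())
        small = np.flatnonzero(sizes < min_size)
        binary &= ~np.isin(comp, small[small > 0])
    if not binary.any():
        warnings.warn("no object above the size floor", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(binary)
    from skimage.feature import peak_local_max
    peaks = peak_local_max(dist, min_distance=int(diameter_px / 2.0),
                           labels=binary)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labeled, _ = ndi.label(binary)
        return labeled.astype(np.int32)
    labels = watershed(-dist, markers, mask=binary)
    return labels.astype(np.int32)


# ---------------------------------------------------------------------------
# Voronoi expansion
# ---------------------------------------------------------------------------


def expand_labels_voronoi(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Expand labels into the background up to ``radius_px``.

    Exact Euclidean nearest-labeled-pixel rule; equidistant ties are won by
    the smaller label.  Original labeled pixels are never changed.
    Implemented as per-label windowed distance transforms scanned in
    ascending label order with strict-improvement updates on integer
    squared distances, which realizes the tie rule exactly.
    """
    if radius_px < 0:
        raise ConfigError("radius must be >= 0")
    mask = np.asarray(mask)
    out = mask.astype(np.int32, copy=True)
    labels = np.unique(mask[mask > 0])
    if radius_px == 0 or labels.size == 0:
        return out
    h, w = mask.shape
    r2max = float(radius_px) ** 2 + 1e-9
    reach = int(np.floor(radius_px)) + 1
    best = np.full(mask.shape, np.iinfo(np.int64).max, dtype=np.int64)
    best[mask > 0] = 0
    for lab in labels:
        ys, xs = np.nonzero(mask == lab)
        win = (slice(max(ys.min() - reach, 0), min(ys.max() + reach + 1, h)),
               slice(max(xs.min() - reach, 0), min(xs.max() + reach + 1, w)))
        sub = mask[win] == lab
        d = ndi.distance_transform_edt(~sub)
        d2 = np.rint(d * d).astype(np.int64)
        sel = (d2 <= r2max) & (d2 < best[win])
        out[win][sel] = lab
        b = best[win]
        b[sel] = d2[sel]
        best[win] = b
    return out


# ---------------------------------------------------------------------------
# Transcript assignment
# ---------------------------------------------------------------------------


@dataclass
class RetentionReport:
    total: int
    assigned: int
    unassigned: int
    out_of_frame: int

    @property
    def retention(self) -> float:
        return self.assigned / self.total if self.total else 0.0


def assign_transcripts(
    spots: pd.DataFrame,
    mask: np.ndarray,
) -> tuple[pd.DataFrame, CountMatrix, RetentionReport]:
    """Assign each spot the mask label at its pixel (0 = unassigned).

    Out-of-frame spots are dropped (counted in the report).  Returns the
    assigned in-frame spot table, a cell x gene count matrix over assigned
    spots, and the retention report
    (assigned + unassigned + out_of_frame = total).
    """
    total = len(spots)
    rows, cols = spot_pixels(spots)
    h, w = mask.shape
    in_frame = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    out_of_frame = int((~in_frame).sum())
    kept = spots.loc[in_frame].copy()
    assigned = mask[rows[in_frame], cols[in_frame]].astype(int)
    kept["assigned_cell"] = assigned

    hit = kept[kept["assigned_cell"] > 0]
    if len(hit):
        tab = pd.crosstab(hit["assigned_cell"], hit["gene"])
        genes = sorted(spots["gene"].unique())
        tab = tab.reindex(columns=genes, fill_value=0)
        cm = CountMatrix(tab.to_numpy(),
                         [f"cell_{c}" for c in tab.index],
                         list(tab.columns), "raw_counts", validate=False)
    else:
        genes = sorted(spots["gene"].unique())
        cm = CountMatrix(np.zeros((0, len(genes)), dtype=int), [], genes,
                         "raw_counts", validate=False)
    report = RetentionReport(
        total=total,
        assigned=int((assigned > 0).sum()),
        unassigned=int((assigned == 0).sum()),
        out_of_frame=out_of_frame,
    )
    return kept.reset_index(drop=True), cm, report


def retention_curve(spots: pd.DataFrame, mask: np.ndarray,
                    radii=(0, 5, 10, 20, 30)) -> pd.DataFrame:
    """Retention fraction as a function of the expansion radius."""
    rows = []
    for r in radii:
        expanded = expand_labels_voronoi(mask, r)
        _, _, rep = assign_transcripts(spots, expanded)
        rows.append((r, rep.assigned, rep.retention))
    return pd.DataFrame(rows, columns=["radius_px", "assigned", "retention"])


# ---------------------------------------------------------------------------
# Co-location analysis
# ---------------------------------------------------------------------------


def coloc_analysis(
    spots: pd.DataFrame,
    set_a,
    set_b,
    radius_px: float,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[int, float]:
    """Count A-spots with a B-spot within ``radius_px``; permutation p.

    The null permutes gene labels over the fixed spot positions.  Returns
    (observed co-occurrence count, one-sided p = (1 + #null >= obs) /
    (1 + n_perm)).
    """
    genes = spots["gene"].to_numpy()
    in_a = np.isin(genes, list(set_a))
    in_b = np.isin(genes, list(set_b))
    if not in_a.any() or not in_b.any():
        raise ValidationError("both gene sets must be present in the table")
    pos = spots[["x", "y"]].to_numpy()

    def count(a_mask: np.ndarray, b_mask: np.ndarray) -> int:
        tree = cKDTree(pos[b_mask])
        d, _ = tree.query(pos[a_mask], k=1,
                          distance_upper_bound=radius_px + 1e-12)
        return int(np.isfinite(d).sum())

    obs = count(in_a, in_b)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(genes))
        if count(in_a[perm], in_b[perm]) >= obs:
            exceed += 1
    return obs, (1 + exceed) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Replicate merging with batch check
# ---------------------------------------------------------------------------


@dataclass
class BatchMixingReport:
    mixing_score: float
    per_cluster: pd.DataFrame = field(default_factory=pd.DataFrame)
    flagged_clusters: list[int] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return len(self.flagged_clusters) == 0


def cluster_spatial_cells(m: CountMatrix, cfg: PipelineConfig,
                          seed: int | None = None) -> ClusterLabeling:
    """Lognorm -> scale -> PCA -> SNN/Leiden for panel-sized matrices."""
    logn = lognormalize(m, cfg.sc_scale_total)
    scaled = scale_matrix(logn)
    n_pcs = min(cfg.sc_n_pcs, min(scaled.shape) - 1)
    emb, _ = run_pca(scaled, n_pcs)
    return cluster_cells(emb, knn_k=min(cfg.snn_k, m.shape[0] - 1),
                         resolution=cfg.leiden_resolution,
                         seed=cfg.rng_seed if seed is None else seed,
                         prune=cfg.snn_prune, cell_ids=m.row_ids)


def merge_replicates(
    samples: list[CountMatrix],
    cfg: PipelineConfig | None = None,
    entropy_threshold: float = 0.5,
    seed: int = 0,
) -> tuple[CountMatrix, pd.Series, ClusterLabeling | None, BatchMixingReport]:
    """Concatenate replicate cell x gene matrices and check batch mixing.

    Cells keep a replicate tag; after joint clustering each cluster's
    replicate composition is compared with the global composition
    (chi-square, BH-corrected) and its normalized entropy computed.  The
    mixing score is the mean normalized entropy over clusters; a cluster is
    flagged when q < 0.05 AND entropy < ``entropy_threshold``.  A single
    replicate passes trivially with score 1.0.
    """
    if not samples:
        raise ValidationError("no replicates given")
    genes = samples[0].col_ids
    for i, s in enumerate(samples[1:], 2):
        if set(s.col_ids) != set(genes):
            raise ValidationError(
                f"replicate {i} gene universe differs from replicate 1")
    merged_vals = np.vstack([
        s.to_dense()[:, s.col_index(genes)] for s in samples]).astype(int)
    tags = np.concatenate([
        np.full(s.shape[0], i) for i, s in enumerate(samples, 1)])
    cell_ids = [f"rep{t}_{c}" for t, s in zip(range(1, len(samples) + 1), samples)
                for c in s.row_ids]
    merged = CountMatrix(merged_vals, cell_ids, genes, "raw_counts",
                         validate=False)
    tag_series = pd.Series(tags, index=cell_ids, name="replicate")

    if len(samples) == 1:
        return merged, tag_series, None, BatchMixingReport(mixing_score=1.0)

    cfg = cfg or default_spatial_config()
    # drop zero-count cells before normalization
    totals = merged_vals.sum(axis=1)
    nonzero = totals > 0
    work = merged.subset(rows=nonzero)
    work_tags = tag_series[nonzero]
    labeling = cluster_spatial_cells(work, cfg, seed=seed)

    n_reps = len(samples)
    global_prop = work_tags.value_counts(normalize=True).reindex(
        range(1, n_reps + 1), fill_value=0.0)
    rows = []
    for c in np.unique(labeling.labels):
        members = work_tags[labeling.labels == c]
        obs = members.value_counts().reindex(range(1, n_reps + 1),
                                             fill_value=0).to_numpy()
        expected = global_prop.to_numpy() * obs.sum()
        ok = expected > 0
        chi2 = ((obs[ok] - expected[ok]) ** 2 / expected[ok]).sum()
        p = float(stats.chi2.sf(chi2, df=max(ok.sum() - 1, 1)))
        prop = obs / obs.sum()
        nzp = prop[prop > 0]
        entropy = float(-(nzp * np.log(nzp)).sum() / np.log(n_reps))
        rows.append((int(c), int(obs.sum()), entropy, p))
    per_cluster = pd.DataFrame(rows, columns=["cluster", "n_cells",
                                              "entropy", "p"])
    per_cluster["q"] = multipletests(per_cluster["p"].to_numpy(),
                                     method="fdr_bh")[1]
    per_cluster["flagged"] = ((per_cluster["q"] < 0.05)
                              & (per_cluster["entropy"] < entropy_threshold))
    report = BatchMixingReport(
        mixing_score=float(per_cluster["entropy"].mean()),
        per_cluster=per_cluster,
        flagged_clusters=per_cluster.loc[per_cluster["flagged"],
                                         "cluster"].tolist(),
    )
    return merged, tag_series, labeling, report


# ---------------------------------------------------------------------------
# Mapping clusters back to space
# ---------------------------------------------------------------------------


def map_clusters_spatial(
    labeling: ClusterLabeling,
    mask: np.ndarray,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell centroid table and a recolored label image.

    Cell ids must be ``cell_<label>`` referring to mask labels.  The
    recolored image paints each cell's pixels with ``cluster + 1`` (0 stays
    background).
    """
    props = {p.label: p for p in regionprops(mask)}
    rows = []
    recolored = np.zeros(mask.shape, dtype=np.int32)
    ann = labeling.annotation or {}
    for cell_id, cluster in zip(labeling.cell_ids, labeling.labels):
        lab = int(str(cell_id).rsplit("_", 1)[-1])
        if lab not in props:
            raise ValidationError(
                f"cell {cell_id!r} (label {lab}) absent from the mask")
        cy, cx = props[lab].centroid
        rows.append((cell_id, lab, float(cx), float(cy), int(cluster),
                     ann.get(int(cluster), "unassigned")))
        recolored[mask == lab] = int(cluster) + 1
    table = pd.DataFrame(rows, columns=["cell", "mask_label", "centroid_x",
                                        "centroid_y", "cluster", "annotation"])
    return table, recolored
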