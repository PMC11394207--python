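"""Shared domain types, configuration, and on-disk format readers/writers.

The pipeline moves count data through three layers (``raw_counts`` ->
``lognorm`` -> ``scaled``) held in :class:`CountMatrix`, spatial transcript
coordinates through :class:`pandas.DataFrame` spot tables, and segmentation
results through integer label masks.  Everything on disk is plain text
(MatrixMarket MTX + TSV, dense CSV, spot TSV) or single-channel TIFF.

Coordinate convention: image origin top-left, ``x`` = column, ``y`` = row,
0-based; a spot at ``(x, y)`` belongs to pixel ``(floor(y), floor(x))``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile

__all__ = [
    "CountMatrix",
    "PipelineConfig",
    "FormatError",
    "ValidationError",
    "ConfigError",
    "GeometryError",
    "EmptyResultError",
    "read_counts",
    "write_counts",
    "read_spot_table",
    "write_spot_table",
    "read_label_mask",
    "write_label_mask",
    "spot_pixels",
]

LAYER_TAGS = ("raw_counts", "lognorm", "scaled")


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(ValueError):
    """In-memory data violate a domain invariant."""


class ConfigError(ValueError):
    """A configuration value is out of its legal range."""


class GeometryError(ValueError):
    """A spatial construction is infeasible (e.g. nuclei cannot be placed)."""


class EmptyResultError(ValueError):
    """An operation produced an empty result where data were required."""


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


class CountMatrix:
    """Labelled 2-D expression matrix.

    Orientation is context-dependent: single-cell matrices are cells x genes,
    bulk matrices genes x samples.  ``layer_tag`` records the transformation
    state; the ``raw_counts`` layer must hold non-negative integers.
    """

    def __init__(self, values, row_ids: Sequence[str], col_ids: Sequence[str],
                 layer_tag: str = "raw_counts", validate: bool = True):
        if sp.issparse(values):
            values = values.tocsr()
        else:
            values = np.asarray(values)
            if values.ndim != 2:
                raise ValidationError("values must be 2-D")
        self.values = values
        self.row_ids = list(map(str, row_ids))
        self.col_ids = list(map(str, col_ids))
        if layer_tag not in LAYER_TAGS:
            raise ValidationError(f"unknown layer_tag {layer_tag!r}")
        self.layer_tag = layer_tag
        if validate:
            self._validate()

    def _validate(self) -> None:
        n, m = self.values.shape
        if len(self.row_ids) != n:
            raise ValidationError(
                f"{len(self.row_ids)} row ids for {n} rows")
        if len(self.col_ids) != m:
            raise ValidationError(
                f"{len(self.col_ids)} col ids for {m} columns")
        if len(set(self.row_ids)) != n:
            raise ValidationError("duplicate row ids")
        if len(set(self.col_ids)) != m:
            raise ValidationError("duplicate col ids")
        data = self.values.data if sp.issparse(self.values) else self.values
        if data.size and self.layer_tag == "raw_counts":
            if np.min(data) < 0:
                raise ValidationError("raw_counts layer contains negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("raw_counts layer contains non-integer entries")

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.values.copy(), list(self.row_ids),
                           list(self.col_ids), self.layer_tag, validate=False)

    def row_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {r: i for i, r in enumerate(self.row_ids)}
        return np.array([lookup[i] for i in ids], dtype=int)

    def col_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.col_ids)}
        return np.array([lookup[i] for i in ids], dtype=int)

    def subset(self, rows=None, cols=None, layer_tag: str | None = None) -> "CountMatrix":
        """Subset by boolean mask or integer index array along either axis."""
        v = self.values
        row_ids, col_ids = self.row_ids, self.col_ids
        if rows is not None:
            rows = np.asarray(rows)
            if rows.dtype == bool:
                rows = np.flatnonzero(rows)
            v = v[rows, :]
            row_ids = [row_ids[i] for i in rows]
        if cols is not None:
            cols = np.asarray(cols)
            if cols.dtype == bool:
                cols = np.flatnonzero(cols)
            v = v[:, cols]
            col_ids = [col_ids[i] for i in cols]
        return CountMatrix(v, row_ids, col_ids,
                           layer_tag or self.layer_tag, validate=False)

    def transpose(self) -> "CountMatrix":
        return CountMatrix(self.values.T, self.col_ids, self.row_ids,
                           self.layer_tag, validate=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.row_ids,
                            columns=self.col_ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"CountMatrix({n}x{m}, layer={self.layer_tag!r})"


# ---------------------------------------------------------------------------
# PipelineConfig
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with study defaults.

    Single-cell QC: genes kept when detected in >= ``sc_min_cells`` cells;
    cells kept with feature counts in [``sc_min_features``,
    ``sc_max_features``] and mitochondrial fraction <=
    ``sc_max_mito_fraction``.  Marker gates follow the 60% detection / 10%
    difference rule; DE significance at 5% FDR; k-means k screened over
    [2, 15] with k = 7 retained; nuclei of ~30 px diameter are expanded by a
    30 px Voronoi radius; probe panels are capped at 100 probes with a
    59-probe design target.
    """

    sc_min_cells: int = 10
    sc_min_features: int = 100
    sc_max_features: int = 2500
    sc_max_mito_fraction: float = 0.05
    sc_scale_total: float = 10000.0
    sc_n_variable: int = 2000
    sc_n_pcs: int = 15
    spatial_n_pcs: int = 17
    marker_min_pct: float = 0.60
    marker_min_diff: float = 0.10
    de_fdr: float = 0.05
    kmeans_k_min: int = 2
    kmeans_k_max: int = 15
    kmeans_k_chosen: int = 7
    expand_radius_px: float = 30.0
    nuclei_diameter_px: float = 30.0
    umap_spread: float = 1.0
    probe_max_count: int = 100
    probe_target: int = 59
    mito_prefix: str = "mt-"
    snn_k: int = 20
    snn_prune: float = 1.0 / 15.0
    leiden_resolution: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sc_max_mito_fraction", "marker_min_pct",
                     "marker_min_diff", "de_fdr", "snn_prune"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("sc_min_cells", "sc_min_features", "sc_max_features",
                     "sc_scale_total", "sc_n_variable", "sc_n_pcs",
                     "spatial_n_pcs", "kmeans_k_chosen", "nuclei_diameter_px",
                     "probe_max_count", "probe_target", "snn_k"):
            v = getattr(self, name)
            if v <= 0:
                raise ConfigError(f"{name} must be strictly positive, got {v}")
        if self.expand_radius_px < 0:
            raise ConfigError("expand_radius_px must be >= 0")
        if self.kmeans_k_min < 2:
            raise ConfigError("kmeans_k_min must be >= 2")
        if self.kmeans_k_max < self.kmeans_k_min:
            raise ConfigError("kmeans_k_max < kmeans_k_min")

    @property
    def k_range(self) -> range:
        return range(self.kmeans_k_min, self.kmeans_k_max + 1)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    # -- flat key=value persistence ---------------------------------------
    def to_file(self, path: str | os.PathLike) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key=value")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in types:
                raise FormatError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = casts[types[key]](val.strip())
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Count matrix I/O
# ---------------------------------------------------------------------------

_MTX_NAMES = ("matrix.mtx", "features.tsv", "barcodes.tsv")


def read_counts(path: str | os.PathLike, layout: str = "mtx_triplet") -> CountMatrix:
    """Read a raw count matrix from disk.

    ``mtx_triplet`` expects a directory holding ``matrix.mtx`` (genes x
    cells, 10x convention), ``features.tsv`` and ``barcodes.tsv``; the
    returned matrix is transposed to cells x genes.  ``dense_csv`` expects a
    comma-separated table with a header row and ids in the first column, and
    is returned in its stored orientation.
    """
    path = Path(path)
    if layout == "mtx_triplet":
        mtx_path, feat_path, bc_path = (path / n for n in _MTX_NAMES)
        for p in (mtx_path, feat_path, bc_path):
            if not p.exists():
                raise FormatError(f"missing file: {p}")
        try:
            mat = scipy.io.mmread(mtx_path)
        except Exception as exc:
            raise FormatError(f"invalid MatrixMarket file {mtx_path}: {exc}") from exc
        features = _read_id_column(feat_path)
        barcodes = _read_id_column(bc_path)
        n_genes, n_cells = mat.shape
        if len(features) != n_genes:
            raise FormatError(
                f"{feat_path}: {len(features)} lines but matrix has {n_genes} rows")
        if len(barcodes) != n_cells:
            raise FormatError(
                f"{bc_path}: {len(barcodes)} lines but matrix has {n_cells} columns")
        mat = sp.csr_matrix(mat.T)
        _check_raw(mat.data, mtx_path)
        return CountMatrix(mat, barcodes, features, "raw_counts")
    if layout == "dense_csv":
        if not path.exists():
            raise FormatError(f"missing file: {path}")
        df = pd.read_csv(path, index_col=0)
        vals = df.to_numpy()
        _check_raw(vals, path)
        return CountMatrix(vals, df.index, df.columns, "raw_counts")
    raise ConfigError(f"unknown layout {layout!r}")


def _read_id_column(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _check_raw(data: np.ndarray, path) -> None:
    if data.size == 0:
        return
    if np.min(data) < 0:
        raise ValidationError(f"{path}: negative count entries")
    if not np.allclose(data, np.round(data)):
        raise ValidationError(f"{path}: non-integer count entries")


def write_counts(m: CountMatrix, path: str | os.PathLike,
                 layout: str = "mtx_triplet") -> None:
    """Write a count matrix; inverse of :func:`read_counts` for each layout."""
    path = Path(path)
    if layout == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        mat = m.values if sp.issparse(m.values) else sp.csr_matrix(m.values)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(mat.T))
        (path / "features.tsv").write_text(
            "".join(f"{g}\n" for g in m.col_ids))
        (path / "barcodes.tsv").write_text(
            "".join(f"{b}\n" for b in m.row_ids))
    elif layout == "dense_csv":
        path.parent.mkdir(parents=True, exist_ok=True)
        m.to_dataframe().to_csv(path)
    else:
        raise ConfigError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# Spot table I/O
# ---------------------------------------------------------------------------

SPOT_COLUMNS = ("gene", "x", "y")


def read_spot_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a transcript spot table (TSV with columns gene, x, y in pixels).

    Row order is preserved.  Coordinates must be finite and non-negative.
    An ``assigned_cell`` column, when present, is read back as integers.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for c in ("x", "y"):
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), c].iloc[0]
            raise ValidationError(f"{path}: non-numeric {c} value {bad!r}")
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValidationError(f"{path}: {c} must be finite and >= 0")
        df[c] = vals.astype(float)
    df["gene"] = df["gene"].astype(str)
    if "assigned_cell" in df.columns:
        df["assigned_cell"] = df["assigned_cell"].astype(int)
    return df.reset_index(drop=True)


def write_spot_table(spots: pd.DataFrame, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    spots.to_csv(path, sep="\t", index=False)


def spot_pixels(spots: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Map spot coordinates to pixel indices: (row, col) = (floor(y), floor(x))."""
    rows = np.floor(spots["y"].to_numpy()).astype(int)
    cols = np.floor(spots["x"].to_numpy()).astype(int)
    return rows, cols


# ---------------------------------------------------------------------------
# Label mask I/O
# ---------------------------------------------------------------------------


def read_label_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a single-channel integer TIFF as a label mask (0 = background)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise FormatError(
            f"{path}: expected single-channel 2-D image, got shape {img.shape}")
    if not np.issubdtype(img.dtype, np.integer):
        raise FormatError(f"{path}: expected integer pixel type, got {img.dtype}")
    return img.astype(np.int32)


def write_label_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    mask = np.asarray(mask)
    if mask.ndim != 2 or not np.issubdtype(mask.dtype, np.integer):
        raise ValidationError("label mask must be a 2-D integer array")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dtype = np.uint16 if mask.max(initial=0) < 2 ** 16 else np.int32
    tifffile.imwrite(path, mask.astype(dtype))
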