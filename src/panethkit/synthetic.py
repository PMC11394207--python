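"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes:

* :func:`generate_sc_counts` - a sorted Paneth-cell scRNA-seq experiment with
  nine latent subtypes: four mature subtypes separated by a graded
  pan-marker (Defa-like) program, a tuft-like subtype, a goblet-like
  subtype, an Olfm4+ immature subtype, and mitochondria-high/-low subtypes.
  Low-quality cells violating the QC rules and a cell-cycle program are
  planted by construction.
* :func:`generate_region_bulk` - duodenum/jejunum/ileum bulk samples built
  as mixtures of the single-cell subtype profiles with per-region weights,
  giving proximal-distal expression gradients.
* :func:`generate_cartography_sample` - a crypt-like nuclei image plus a
  transcript spot table: Gaussian-profile nuclei, perinuclear transcript
  clouds (a fraction inside the nucleus, the rest in a cytoplasmic
  annulus), and uniform background spots.

Counts are negative binomial with mean mu and dispersion alpha
(variance mu + alpha * mu^2), matching the parameterization of the bulk
differential-expression test so parameter recovery is self-consistent.
All generators are pure functions of their arguments and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    CountMatrix,
    GeometryError,
)

__all__ = [
    "ScTruth",
    "RegionTruth",
    "CartographyTruth",
    "SUBTYPE_NAMES",
    "REGIONS",
    "generate_sc_counts",
    "default_region_truth",
    "generate_region_bulk",
    "generate_cartography_sample",
]

#: Canonical subtype palette (order fixed; indices are the truth labels).
SUBTYPE_NAMES = (
    "mature_1", "mature_2", "mature_3", "mature_4",
    "tuft_like", "goblet_like", "immature", "mito_high", "mito_low",
)

#: Annotation label each planted subtype should receive.
SUBTYPE_ANNOTATION = {
    "mature_1": "mature_PC", "mature_2": "mature_PC",
    "mature_3": "mature_PC", "mature_4": "mature_PC",
    "tuft_like": "TC_PC", "goblet_like": "GC_PC",
    "immature": "immature_PC", "mito_high": "mito_high",
    "mito_low": "mito_low",
}

REGIONS = ("duodenum", "jejunum", "ileum")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# Single-cell truth
# ---------------------------------------------------------------------------


@dataclass
class ScTruth:
    """Ground truth for a synthetic single-cell count matrix."""

    cell_labels: np.ndarray            # per-cell subtype index
    subtype_names: tuple[str, ...]
    subtype_profiles: np.ndarray       # subtype x gene relative means
    gene_names: list[str]
    marker_sets: dict[str, list[str]]  # subtype name -> planted marker genes
    pan_markers: list[str]
    mito_genes: list[str]
    s_genes: list[str]
    g2m_genes: list[str]
    cycling_cells: np.ndarray          # cell indices with the cycle program
    planted_low_quality: np.ndarray    # cell indices violating >= 1 QC rule
    cell_ids: list[str] = field(default_factory=list)

    @property
    def annotation_signatures(self) -> dict[str, list[str]]:
        """Signature gene sets for cluster annotation (discrete subtypes only)."""
        return {
            "TC_PC": self.marker_sets["tuft_like"],
            "GC_PC": self.marker_sets["goblet_like"],
            "immature_PC": self.marker_sets["immature"],
        }

    def labels_for(self, cell_ids) -> np.ndarray:
        lookup = dict(zip(self.cell_ids, self.cell_labels))
        return np.array([lookup[c] for c in cell_ids], dtype=int)


def generate_sc_counts(
    n_cells: int = 3000,
    n_genes: int = 1500,
    n_subtypes: int = 9,
    effect_fold: float = 6.0,
    nb_dispersion: float = 0.25,
    seed: int = 0,
    markers_per_subtype: int = 10,
    n_pan_markers: int = 60,
    n_mito_genes: int = 20,
    n_cycle_genes: int = 10,
    cycling_fraction: float = 0.10,
    low_quality_fraction: float = 0.05,
    mean_library_size: float = 5000.0,
) -> tuple[CountMatrix, ScTruth]:
    """Simulate a cells x genes raw count matrix with planted structure.

    Each subtype carries ``markers_per_subtype`` exclusive markers at mean
    fold ``effect_fold`` over the other subtypes.  Pan markers (Lyz1-like and
    a Defa-like block) are expressed in every subtype, with graded levels
    across the four mature subtypes so that even those are separable.  The
    mitochondrial block's share of each cell's library is Beta-distributed
    (subtype-specific mean; planted low-quality cells use a shifted Beta
    above the 5% QC cut-off, or a collapsed library below the minimum
    feature count).
    """
    if n_subtypes < 2:
        raise ConfigError("n_subtypes must be >= 2")
    if effect_fold < 1:
        raise ConfigError("effect_fold must be >= 1")
    if nb_dispersion <= 0:
        raise ConfigError("nb_dispersion must be > 0")
    budget = (n_mito_genes + n_pan_markers + 2 * n_cycle_genes
              + n_subtypes * markers_per_subtype)
    if budget >= n_genes:
        raise ConfigError(
            f"marker budget ({budget}) exceeds n_genes ({n_genes}); "
            "reduce n_subtypes or markers_per_subtype")

    rng = np.random.default_rng(seed)
    names = list(SUBTYPE_NAMES[:n_subtypes]) if n_subtypes <= len(SUBTYPE_NAMES) \
        else list(SUBTYPE_NAMES) + [f"extra_{i}" for i in range(n_subtypes - len(SUBTYPE_NAMES))]

    # -- gene universe ------------------------------------------------------
    gene_names: list[str] = []
    mito_genes = [f"mt-{i + 1}" for i in range(n_mito_genes)]
    gene_names += mito_genes
    pan_markers = ["Lyz1"] + [f"Defa{i + 1}" for i in range(n_pan_markers - 1)]
    gene_names += pan_markers
    s_genes = [f"Sphase{i + 1}" for i in range(n_cycle_genes)]
    g2m_genes = [f"G2m{i + 1}" for i in range(n_cycle_genes)]
    gene_names += s_genes + g2m_genes
    canonical = {
        "tuft_like": ["Dclk1", "St18", "Rgs13"],
        "goblet_like": ["Fcgbp", "Tff3", "Agr2"],
        "immature": ["Olfm4", "Lgr5"],
    }
    marker_sets: dict[str, list[str]] = {}
    for s, name in enumerate(names):
        base = canonical.get(name, [])
        ms = list(base[:markers_per_subtype])
        ms += [f"{name}_mk{j + 1}" for j in range(markers_per_subtype - len(ms))]
        marker_sets[name] = ms
        gene_names += ms
    n_background = n_genes - len(gene_names)
    gene_names += [f"gene{i + 1}" for i in range(n_background)]

    # -- subtype mean profiles (relative, non-mito genes) -------------------
    idx = {g: i for i, g in enumerate(gene_names)}
    profiles = np.zeros((n_subtypes, n_genes))
    background_means = rng.lognormal(mean=0.0, sigma=1.0, size=n_background)
    bg_start = n_genes - n_background
    profiles[:, bg_start:] = background_means[None, :]

    # pan markers: expressed everywhere; levels graded across the mature
    # subtypes (Defa-like combinatorial grading, orientation random per
    # gene).  Amplitudes are moderate relative to the between-gene spread
    # so pseudo-bulk/bulk correlations stay high for every subtype, as in
    # real region data.
    pan_base = rng.lognormal(mean=1.2, sigma=0.8, size=len(pan_markers))
    mature = [i for i, nm in enumerate(names) if nm.startswith("mature")]
    grade_levels = np.geomspace(0.6, 1.6, num=max(len(mature), 1))
    for j, g in enumerate(pan_markers):
        col = idx[g]
        profiles[:, col] = pan_base[j]
        order = rng.permutation(len(mature))
        for rank, s in enumerate(np.array(mature)[order]):
            profiles[s, col] = pan_base[j] * grade_levels[rank]

    # subtype-exclusive markers at effect_fold over baseline.
    marker_base = 2.0
    for s, name in enumerate(names):
        for g in marker_sets[name]:
            col = idx[g]
            profiles[:, col] = marker_base
            profiles[s, col] = marker_base * effect_fold

    # cycle genes: low baseline everywhere (boost applied per cycling cell).
    for g in s_genes + g2m_genes:
        profiles[:, idx[g]] = 0.5

    # mito genes carry relative weights only; their library share is planted.
    mito_weights = rng.dirichlet(np.full(n_mito_genes, 5.0))

    # -- cells ---------------------------------------------------------------
    labels = rng.integers(0, n_subtypes, size=n_cells)
    libraries = rng.lognormal(mean=np.log(mean_library_size), sigma=0.25,
                              size=n_cells)

    n_low = int(round(low_quality_fraction * n_cells))
    low_quality = rng.choice(n_cells, size=n_low, replace=False)
    high_mito = low_quality[: n_low // 2]
    low_feature = low_quality[n_low // 2:]
    # total counts bounded well below the 100-feature floor, so the
    # detected-gene count (<= total counts) violates the rule by construction
    libraries[low_feature] = rng.uniform(30, 75, size=low_feature.size)

    # mitochondrial library share: Beta with subtype-specific mean.
    mito_mean = np.full(n_cells, 0.015)
    for s, name in enumerate(names):
        if name == "mito_high":
            mito_mean[labels == s] = 0.040
        elif name == "mito_low":
            mito_mean[labels == s] = 0.004
    mito_mean[high_mito] = 0.15
    conc = 400.0
    mito_frac = rng.beta(mito_mean * conc, (1 - mito_mean) * conc)

    cycling = rng.choice(n_cells, size=int(round(cycling_fraction * n_cells)),
                         replace=False)
    cycle_cols = np.array([idx[g] for g in s_genes + g2m_genes])

    # per-cell expected counts
    mu = profiles[labels].astype(float)
    mu[np.ix_(cycling, cycle_cols)] *= 12.0
    mu[:, : n_mito_genes] = 0.0
    row_sums = mu.sum(axis=1)
    mu *= ((1.0 - mito_frac) * libraries / row_sums)[:, None]
    mu[:, : n_mito_genes] = np.outer(mito_frac * libraries, mito_weights)

    counts = _nb_sample(rng, mu, nb_dispersion)
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]

    truth = ScTruth(
        cell_labels=labels,
        subtype_names=tuple(names),
        subtype_profiles=profiles,
        gene_names=gene_names,
        marker_sets=marker_sets,
        pan_markers=pan_markers,
        mito_genes=mito_genes,
        s_genes=s_genes,
        g2m_genes=g2m_genes,
        cycling_cells=np.sort(cycling),
        planted_low_quality=np.sort(low_quality),
        cell_ids=cell_ids,
    )
    m = CountMatrix(counts, cell_ids, gene_names, "raw_counts", validate=False)
    return m, truth


# ---------------------------------------------------------------------------
# Region bulk truth
# ---------------------------------------------------------------------------


@dataclass
class RegionTruth:
    """Mixture design for regional bulk samples."""

    mixing_weights: pd.DataFrame   # regions x subtypes, rows sum to 1
    region_depths: dict[str, float]
    n_replicates: int = 3

    def __post_init__(self) -> None:
        w = self.mixing_weights.to_numpy()
        if (w < 0).any():
            raise ConfigError("mixing weights must be non-negative")
        if not np.allclose(w.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigError("mixing weights must sum to 1 per region")
        for r, d in self.region_depths.items():
            if d <= 0:
                raise ConfigError(f"zero or negative depth for region {r!r}")


def default_region_truth(
    subtype_names: tuple[str, ...] = SUBTYPE_NAMES,
    dominant_weight: float = 0.7,
    depth: float = 1e6,
    n_replicates: int = 3,
) -> RegionTruth:
    """Study-condition mixture: one dominant mature subtype per region.

    mature_1 dominates the duodenum, mature_2 the jejunum, mature_3 the
    ileum (weight ``dominant_weight``); the other two region-dominant
    matures contribute a trace; every remaining subtype has the same weight
    in all three regions and is therefore 'uniform' along the axis.
    """
    n = len(subtype_names)
    w = pd.DataFrame(0.0, index=list(REGIONS), columns=list(subtype_names))
    dominant = {"duodenum": "mature_1", "jejunum": "mature_2",
                "ileum": "mature_3"}
    trace = 0.015
    uniform = [s for s in subtype_names if s not in dominant.values()]
    for region in REGIONS:
        w.loc[region, dominant[region]] = dominant_weight
        for other in dominant.values():
            if other != dominant[region]:
                w.loc[region, other] = trace
        rest = 1.0 - dominant_weight - 2 * trace
        for s in uniform:
            w.loc[region, s] = rest / len(uniform)
    return RegionTruth(
        mixing_weights=w,
        region_depths={r: depth for r in REGIONS},
        n_replicates=n_replicates,
    )


def generate_region_bulk(
    truth: ScTruth,
    region_truth: RegionTruth,
    seed: int = 0,
    nb_dispersion: float = 0.05,
) -> tuple[CountMatrix, pd.Series]:
    """Simulate genes x samples bulk counts as subtype-profile mixtures.

    Sample means are sum_c w_rc * profile_c (the profile renormalized to
    proportions, mito block included at each subtype's nominal share),
    rescaled to the sample's depth, with NB noise.  Returns the count matrix
    and a per-sample region label series.
    """
    w = region_truth.mixing_weights
    profiles = truth.subtype_profiles.astype(float).copy()
    # fold the mitochondrial block in at a nominal 1.5% library share
    n_mito = len(truth.mito_genes)
    nonmito_sum = profiles[:, n_mito:].sum(axis=1, keepdims=True)
    profiles[:, :n_mito] = (0.015 / 0.985) * nonmito_sum / n_mito
    props = profiles / profiles.sum(axis=1, keepdims=True)

    rng = np.random.default_rng(seed)
    sample_ids, regions, cols = [], [], []
    sub_order = [truth.subtype_names.index(s) for s in w.columns]
    for region in w.index:
        depth = region_truth.region_depths[region]
        mix = w.loc[region].to_numpy() @ props[sub_order]
        for rep in range(region_truth.n_replicates):
            mu = mix * depth
            cols.append(_nb_sample(rng, mu, nb_dispersion))
            sample_ids.append(f"{region}_{rep + 1}")
            regions.append(region)
    counts = np.column_stack(cols)
    m = CountMatrix(counts, truth.gene_names, sample_ids, "raw_counts",
                    validate=False)
    return m, pd.Series(regions, index=sample_ids, name="region")


def generate_profile_archetype_bulk(
    seed: int = 0,
    genes_per_archetype: int = 60,
    within_arc_spread_deg: float = 15.0,
    pattern_strength: float = 1.0,
    nb_dispersion: float = 0.005,
    n_replicates: int = 3,
    log_mean: float = 5.5,
    log_sigma: float = 0.8,
) -> tuple[CountMatrix, pd.Series, np.ndarray]:
    """Bulk counts with coarse-3 / fine-7 regional profile structure.

    A z-scaled 3-point regional profile lives on a circle in the plane
    orthogonal to (1,1,1); archetypes are placed as seven angles grouped in
    three arcs (3 duodenum-high, 1 jejunum-high, 3 ileum-high variants,
    ``within_arc_spread_deg`` apart within an arc), so k-means diagnostics
    have a global optimum at k = 3 (the number of regions) and a second
    local optimum at k = 7.  Returns (genes x samples counts, per-sample
    region labels, per-gene archetype index).
    """
    rng = np.random.default_rng(seed)
    e1 = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
    e2 = np.array([1.0, 1.0, -2.0]) / np.sqrt(6)
    angles: list[float] = []
    for i, arc in enumerate((90.0, 210.0, 330.0)):
        if i == 1:
            angles.append(arc)
        else:
            angles += [arc - within_arc_spread_deg, arc,
                       arc + within_arc_spread_deg]
    patterns = [np.cos(np.radians(t)) * e1 + np.sin(np.radians(t)) * e2
                for t in angles]
    n_genes = genes_per_archetype * len(patterns)
    base = rng.lognormal(log_mean, log_sigma, size=n_genes)
    rows, truth = [], []
    gi = 0
    for k, p in enumerate(patterns):
        mult = np.repeat(np.exp(pattern_strength * p), n_replicates)
        for _ in range(genes_per_archetype):
            rows.append(_nb_sample(rng, base[gi] * mult, nb_dispersion))
            truth.append(k)
            gi += 1
    samples = [f"{r}_{j + 1}" for r in REGIONS for j in range(n_replicates)]
    regions = pd.Series([s.rsplit("_", 1)[0] for s in samples], index=samples,
                        name="region")
    m = CountMatrix(np.array(rows), [f"g{i}" for i in range(n_genes)],
                    samples, "raw_counts", validate=False)
    return m, regions, np.array(truth)


# ---------------------------------------------------------------------------
# Molecular-cartography sample
# ---------------------------------------------------------------------------


@dataclass
class CartographyTruth:
    """Ground truth for a synthetic cartography sample."""

    label_mask: np.ndarray          # true nuclei, labels 1..n
    centers: np.ndarray             # (n, 2) array of (row, col) centers
    cell_types: np.ndarray          # per-cell type index (cell k -> index k-1)
    type_names: tuple[str, ...]
    spot_origin: np.ndarray         # per-spot source cell label, 0 = noise
    cytoplasm_radius_px: float
    gene_names: list[str] = field(default_factory=list)
    marker_sets: dict[str, list[str]] = field(default_factory=dict)


def _place_centers(rng: np.random.Generator, n: int, frame: int,
                   margin: float, min_sep: float,
                   max_tries: int = 200_000) -> np.ndarray:
    lo, hi = margin, frame - margin
    if hi <= lo:
        raise GeometryError("frame too small for the requested margin")
    centers: list[np.ndarray] = []
    placed = np.empty((0, 2))
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise GeometryError(
                f"placed only {len(centers)}/{n} nuclei after {max_tries} "
                "attempts; use fewer nuclei or a larger frame")
        c = rng.uniform(lo, hi, size=2)
        if placed.size and (np.linalg.norm(placed - c, axis=1) < min_sep).any():
            continue
        centers.append(c)
        placed = np.array(centers)
    return placed


def generate_cartography_sample(
    n_nuclei: int = 60,
    frame_px: int = 1400,
    noise_spot_fraction: float = 0.02,
    seed: int = 0,
    n_types: int = 4,
    nuclei_diameter_px: float = 30.0,
    cytoplasm_radius_px: float = 80.0,
    f_nuc: float = 0.2,
    mean_spots_per_cell: float = 80.0,
    markers_per_type: int = 10,
    n_shared_genes: int = 10,
    marker_weight: float = 12.0,
    min_separation_px: float | None = None,
) -> tuple[np.ndarray, CartographyTruth, pd.DataFrame]:
    """Simulate a nuclei image, its ground truth, and a transcript spot table.

    Nuclei are Gaussian intensity bumps of ~``nuclei_diameter_px`` diameter
    on a noisy background.  Each cell draws ~``mean_spots_per_cell`` spots
    from its type's gene profile; a fraction ``f_nuc`` land uniformly inside
    the nucleus disk and the rest uniformly (by area) in the cytoplasmic
    annulus out to ``cytoplasm_radius_px`` from the center.  Background
    noise spots are uniform over the frame.

    The default center separation keeps every cell's cytoplasm outside any
    other cell's 30 px expansion reach, so transcript-to-cell assignment has
    an unambiguous truth.
    """
    r_nuc = nuclei_diameter_px / 2.0
    # cytoplasm_radius below the nucleus radius degenerates to a pure
    # in-nucleus cloud (the annulus is empty)
    r_cyto = max(cytoplasm_radius_px, r_nuc)
    if min_separation_px is None:
        # foreign expanded territories (reach = r_nuc + 30) never overlap
        # the cytoplasm cloud
        min_separation_px = r_cyto + r_nuc + 30.0 + 1.0
    rng = np.random.default_rng(seed)
    sigma = nuclei_diameter_px / 4.0
    # keep the whole spot cloud and the rendered Gaussian inside the frame
    margin = max(r_cyto, 3.0 * sigma, r_nuc) + 2.0
    centers = _place_centers(rng, n_nuclei, frame_px, margin, min_separation_px)

    # -- truth mask: disks of radius r_nuc ---------------------------------
    mask = np.zeros((frame_px, frame_px), dtype=np.int32)
    rr = int(np.ceil(r_nuc))
    yy, xx = np.mgrid[-rr:rr + 1, -rr:rr + 1]
    disk = (yy ** 2 + xx ** 2) <= r_nuc ** 2
    for k, (cy, cx) in enumerate(centers, start=1):
        iy, ix = int(round(cy)), int(round(cx))
        sl = (slice(iy - rr, iy + rr + 1), slice(ix - rr, ix + rr + 1))
        mask[sl][disk] = k

    # -- image: background noise + Gaussian nuclei --------------------------
    img = rng.normal(0.08, 0.02, size=(frame_px, frame_px))
    gr = int(np.ceil(3 * sigma))
    gy, gx = np.mgrid[-gr:gr + 1, -gr:gr + 1]
    bump = np.exp(-(gy ** 2 + gx ** 2) / (2 * sigma ** 2))
    for cy, cx in centers:
        iy, ix = int(round(cy)), int(round(cx))
        sl = (slice(iy - gr, iy + gr + 1), slice(ix - gr, ix + gr + 1))
        img[sl] += 0.85 * bump
    img = np.clip(img, 0.0, None)
    img /= img.max()

    # -- gene panel and type profiles ---------------------------------------
    type_names = tuple(["PC", "GC", "TC", "stem"][:n_types]) if n_types <= 4 \
        else tuple(f"type{i}" for i in range(n_types))
    gene_names: list[str] = []
    marker_sets: dict[str, list[str]] = {}
    for t in type_names:
        ms = [f"{t}_mk{j + 1}" for j in range(markers_per_type)]
        marker_sets[t] = ms
        gene_names += ms
    gene_names += [f"shared{j + 1}" for j in range(n_shared_genes)]
    n_panel = len(gene_names)
    profiles = np.ones((n_types, n_panel))
    for t_idx, t in enumerate(type_names):
        for g in marker_sets[t]:
            profiles[t_idx, gene_names.index(g)] = marker_weight
    profiles /= profiles.sum(axis=1, keepdims=True)

    cell_types = rng.integers(0, n_types, size=n_nuclei)

    # -- spots ---------------------------------------------------------------
    genes, xs, ys, origin = [], [], [], []
    for k, (cy, cx) in enumerate(centers, start=1):
        n_spots = rng.poisson(mean_spots_per_cell)
        if n_spots == 0:
            continue
        g_idx = rng.choice(n_panel, size=n_spots, p=profiles[cell_types[k - 1]])
        in_nuc = (rng.random(n_spots) < f_nuc) | (r_cyto <= r_nuc)
        r = np.empty(n_spots)
        u = rng.random(n_spots)
        # stay 2.5 px inside the nominal radius so rasterization (pixel
        # flooring + center rounding) never pushes an in-nucleus spot
        # outside the mask disk
        r_in = max(r_nuc - 2.5, 1.0)
        r[in_nuc] = r_in * np.sqrt(u[in_nuc])
        r[~in_nuc] = np.sqrt(r_nuc ** 2 + u[~in_nuc]
                             * (r_cyto ** 2 - r_nuc ** 2))
        theta = rng.uniform(0, 2 * np.pi, size=n_spots)
        ys.append(cy + r * np.sin(theta))
        xs.append(cx + r * np.cos(theta))
        genes.append(np.array(gene_names)[g_idx])
        origin.append(np.full(n_spots, k))
    n_cell_spots = sum(a.size for a in origin)
    if noise_spot_fraction > 0:
        n_noise = rng.poisson(
            noise_spot_fraction / (1 - noise_spot_fraction) * n_cell_spots)
        if n_noise:
            genes.append(np.array(gene_names)[
                rng.integers(0, n_panel, size=n_noise)])
            ys.append(rng.uniform(0, frame_px - 1e-9, size=n_noise))
            xs.append(rng.uniform(0, frame_px - 1e-9, size=n_noise))
            origin.append(np.zeros(n_noise, dtype=int))
    spots = pd.DataFrame({
        "gene": np.concatenate(genes),
        "x": np.concatenate(xs),
        "y": np.concatenate(ys),
    })
    # shuffle so spot order carries no information
    perm = rng.permutation(len(spots))
    spots = spots.iloc[perm].reset_index(drop=True)
    origin_arr = np.concatenate(origin)[perm]

    truth = CartographyTruth(
        label_mask=mask,
        centers=centers,
        cell_types=cell_types,
        type_names=type_names,
        spot_origin=origin_arr,
        cytoplasm_radius_px=cytoplasm_radius_px,
        gene_names=gene_names,
        marker_sets=marker_sets,
    )
    return img, truth, spots
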