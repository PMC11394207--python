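# Methods

This note documents the models, parameter choices and numerical decisions
behind each `panethkit` stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Single-cell stage

**QC.** Three ordered filters on the raw count matrix: genes detected in
fewer than `sc_min_cells` (10) cells are removed first; then cells with a
detected-feature count outside [`sc_min_features` = 100,
`sc_max_features` = 2500]; then cells whose mitochondrial count fraction
exceeds `sc_max_mito_fraction` = 0.05. Metrics are computed on the
gene-filtered matrix, so the feature count a cell is judged by excludes
rare genes. Mitochondrial genes are recognized by a configurable name
prefix (default `mt-`) or an explicit gene set.

**Normalization.** `lognorm = ln(1 + 10,000 · x / cell_total)`. This makes
`Σ expm1(·) = 10,000` per cell exactly, which the tests assert at 1e-6
relative tolerance. Cells with zero totals must be removed by QC first.

**Variable genes.** A vst-style ranking: a quadratic trend of log10
variance on log10 mean is fitted across genes, counts are standardized
with the trend's expected standard deviation and clipped at √n_cells, and
genes are ranked by the variance of the clipped values. The trend fit is
written in-repo because the environment's scanpy build cannot provide this
flavor; ties break by input gene order so the ranking is deterministic.

**Cell-cycle regression.** S and G2M scores are mean per-gene z-scores
over the respective gene sets (absent genes dropped with a warning; an
empty set simply drops that covariate). Each gene's z-scores are replaced
by OLS residuals on the available scores, re-standardized, and clipped at
±10 (the same ±10 clip applies when scaling without regression — a
standard outlier guard ahead of PCA). With heterogeneous cell populations
the scores partially absorb compositional differences between subtypes;
this is inherent to score-based regression and the tests therefore check
the no-op property on homogeneous data.

**PCA and jackstraw.** Full-SVD PCA (deterministic up to component sign);
15 components by default for scRNA, 17 for spatial panels. The jackstraw
test permutes a random 10% of genes per round (100 rounds), recomputes the
PCA, pools the permuted genes' absolute loadings per component as a null,
and compares the observed loading distribution against it (one-sided
rank-sum). Significant PCs are returned as a prefix — the first
non-significant component truncates — matching how a "first m PCs" cut is
used downstream. The pipeline default keeps the first 15 PCs; the
jackstraw is available for choosing that cut on new data.

**Clustering.** k-nearest-neighbor graph (k = 20, self included),
shared-nearest-neighbor Jaccard weights `|N_i ∩ N_j| / |N_i ∪ N_j|`
pruned below 1/15, Leiden partition (RB-configuration quality) at
resolution 0.8 with an explicit seed. The named algorithm fixes the
method; k, the pruning threshold and the resolution are artifact defaults
(configurable) because no canonical values exist for them. Labels are
relabeled by decreasing cluster size.

**Markers.** One cluster vs the rest. Gates: `max(pct_in, pct_out) ≥ 0.60`
and `|pct_in − pct_out| ≥ 0.10` — the second gate is the
detection-fraction-difference reading of the "10% significant difference"
rule, matching min.pct/min.diff.pct semantics of the cited tooling.
Gated genes get a two-sided Wilcoxon rank-sum on log-normalized values:
exact by full enumeration of group assignments when C(n, n₁) ≤ 20,000
(midranks for ties; p is the fraction of assignments whose rank-sum
deviates at least as much as observed), tie-corrected normal approximation
otherwise. log2FC compares `expm1` means with a +1 pseudocount. BH
correction is pooled across all clusters' tests as one family — the
conservative, deterministic choice where the original tooling is
ambiguous. Singleton clusters are skipped with a warning.

**Annotation.** Per cluster: mitochondrial expression relative to the
cross-cluster median decides `mito_high` (> 2×) and `mito_low` (< 0.5×)
first; otherwise the argmax signature (mean z over the gene set) wins if
it beats the runner-up by a margin of 0.25 z-units and is positive, else
the cluster falls back to `mature_PC`. Ratio thresholds rather than
absolute fractions keep the rule invariant to panel composition.
A non-destructive doublet flag marks cells above the 99.5th total-count
percentile that score > 1 z on at least two signatures.

## Bulk stage

**Size factors.** Median-of-ratios over genes with nonzero counts in
every sample.

**NB Wald test.** Counts are normalized by size factors; per-gene
dispersion is the moment estimate `(s² − μ̄)/μ̄²` from the pooled
within-group variance, floored at `1e-8` *and* at the median dispersion of
a mean-quantile bin of similarly expressed genes. The trended floor is
deliberate: the raw moment estimate at 3-vs-3 replicates underestimates
dispersion for roughly half the genes and inflates the Wald statistic
(~11% of null genes at nominal 5%); flooring restores calibration
(~5%) while leaving large dispersion estimates — and hence power —
untouched. This is a floor, not shrinkage: estimates are never pulled
down. Group means are the closed-form NB-GLM estimates; when a group is
all-zero for a gene its mean is floored at half a normalized count so
log2FC stays finite (genes all-zero in both groups are excluded). The
standard error follows the NB Fisher information,
`Var(log μ̂) = Σⱼ(1/sⱼ)/(n²μ̂) + α̂/n` per group; p-values are two-sided
normal and q-values BH. No dispersion shrinkage toward a fitted trend, no
independent filtering, no LFC shrinkage — the test is intentionally fully
specified in-repo and is not expected to reproduce reference DE tools
numerically.

**Profile grouping.** Per-gene profiles are log1p CPM averaged per region
(3 values per gene; per-sample profiles available via `profile_by`),
z-scaled per gene. k-means (10 restarts, best within-SS) is screened over
k ∈ [2, 15] with within-SS (elbow), mean Euclidean silhouette and the gap
statistic, `Gap(k) = ⟨log W*ₖ⟩ − log Wₖ`, with uniform references drawn in
the PCA-aligned bounding box (B = 50 by default; smaller B is used where
gap only breaks ties). k = 1 anchors the elbow and gap baselines;
silhouette is undefined there and reported as NaN.

**k selection.** Local optima of the silhouette curve (plateau runs keep
their smallest k) are ranked by silhouette, ties broken by gap then by
smaller k. `global_optimum` returns the best; `nth_local_optimum(2)` is
the finer-granularity rule that prefers a second, finer structure (k = 7)
when the global optimum sits at the number of regions (k = 3).

## Integration stage

Pseudo-bulk rows are integer per-cluster sums plus an all-cells aggregate;
the conservation identity (cluster sums = aggregate) is exact. Profiles
are compared on log1p CPM over the intersection of the DEG set with the
shared genes (error below 3 genes, warning below 10); bulk samples are
averaged per region after the transform (per-sample correlation is one
call away). Pearson is the default; Spearman is available. "GLM-style"
mixture recovery is realized as non-negative least squares of a sample's
log1p-CPM vector on cluster profiles, renormalized to sum to one — the
family/link of the original description is unspecified, and NNLS gives
interpretable weights with a testable recovery property (mean absolute
weight error ≤ 0.1 under the default mixture conditions). The assignment
rule takes all regions within 0.05 (absolute correlation units) of the
row maximum: one region → that label, two adjacent regions (in
duodenum–jejunum–ileum order) → a joint label, and anything else —
all three, or a non-adjacent pair — → `uniform`.

## Spatial stage

**Preprocessing.** Tiles are stitched row-major; background is estimated
by a grayscale opening (minimum then maximum filter, square window of
half-width 25 px — a rolling-ball-style estimate), subtracted, and the
result rescaled to [0, 1].

**Segmentation.** The built-in segmenter is classical: Gaussian smoothing
at σ = diameter/6, Otsu threshold, hole filling, removal of objects below
0.2·π(d/2)², then a distance-transform watershed with peak separation
≥ diameter/2 (expected diameter 30 px). It is a deterministic baseline for
synthetic and clean real images; masks from any external segmenter can be
supplied instead through `read_label_mask`.

**Voronoi expansion.** "Enlarged by 30 px" is read as an expansion
*radius* of 30 px from the nucleus boundary. Every background pixel
within the radius of a labeled pixel takes the label of the nearest one;
equidistant ties go to the smaller label. The implementation scans labels
in ascending order with windowed exact Euclidean distance transforms and
strict-improvement updates on *integer squared distances*, which makes
the tie rule exact and the result identical to the brute-force
nearest-labeled-pixel oracle on every pixel. Because Voronoi territories
are disjoint, a transcript can never be claimed by two cells.

**Assignment and retention.** A spot at (x, y) belongs to pixel
(⌊y⌋, ⌊x⌋); out-of-frame spots are dropped and counted. Retention is the
assigned fraction of all spots; it is non-decreasing in the expansion
radius and equals the in-nucleus fraction at radius 0.

**Batch check.** Replicates are concatenated with tags, clustered with the
spatial defaults, and each cluster's replicate composition is compared to
the global composition (chi-square, BH). The mixing score is the mean
normalized entropy of per-cluster replicate proportions; a cluster is
flagged when q < 0.05 *and* entropy < 0.5, so mild size imbalances in
well-mixed clusters do not flag. Spatial QC defaults are relaxed
(feature floor 5, gene floor 3 cells, 17 PCs) because targeted panels have
≤ ~100 genes and scRNA thresholds do not transfer.

**Mapping.** Cluster identities are painted back as `cluster + 1` (0 stays
background) and per-cell centroids are pixel means.

## Synthetic data

`generate_sc_counts` plants nine subtypes: four mature subtypes that share
a 60-gene pan-marker block (a Lyz1-like gene plus a Defa-like family) with
per-gene graded levels (×0.6–×1.6, orientation random per gene), and five
discrete subtypes (tuft-like, goblet-like, Olfm4⁺ immature, mito-high,
mito-low), each with 10 exclusive markers at 6-fold over baseline. The
mitochondrial block's share of each cell's library is Beta-distributed
(concentration 400) around subtype means of 1.5% (4% mito-high, 0.4%
mito-low); planted low-quality cells use either a 15% mito share or a
30–75-count library so they violate a QC rule by construction. A
10%-of-cells cycling program boosts 20 cycle genes 12-fold. Counts are
NB(μ, α) with variance μ + αμ², the same parameterization as the DE test.
Grade amplitudes are kept moderate relative to between-gene spread so
that pseudo-bulk/bulk correlations stay high for every subtype, as in
real regional data.

`generate_region_bulk` mixes the subtype profiles with per-region weights
(default: one dominant mature subtype per region at 0.7, traces of the
other two, everything else at identical weights in all regions — the
"uniform along the axis" group), rescales to a 10⁶ depth and adds NB
noise (α = 0.05, three replicates per region).

`generate_cartography_sample` draws non-overlapping nuclei (30 px
diameter Gaussian bumps, truth mask of 15 px disks), per-cell transcript
clouds (~80 spots; fraction `f_nuc` = 0.2 uniform inside the nucleus with
a 2.5 px rasterization margin, the rest uniform-by-area in an annulus out
to 80 px from the center) and 2% uniform background spots. The default
center separation (cytoplasm radius + expansion reach + 1 px) guarantees
no cell's transcripts fall inside another cell's expanded territory, so
spot-assignment accuracy has an unambiguous truth; with these geometry
defaults, pre-expansion retention lands near 20% and 30 px expansion
raises it to the low-to-mid 40s — the regime the cell-based analysis is
designed for. `generate_profile_archetype_bulk` places seven regional
profile archetypes as angles on the z-scored-profile circle, grouped in
three arcs (3 duodenal, 1 jejunal, 3 ileal variants, 15° apart within an
arc), producing a silhouette curve with its global optimum at k = 3 and a
second local optimum at k = 7.

What the generators do **not** emulate: ambient RNA, doublet expression
mixtures, batch chemistry effects, realistic gene counts (~55k annotated
genes) or gene names beyond the planted aliases, overlapping or
irregularly shaped nuclei, tissue autofluorescence, or crypt/villus
anatomy. Tests passing on this data therefore demonstrate the
correctness and calibration of the algorithms under their stated
assumptions — not robustness to every artifact of real tissue data.

## Problem sizes and tolerances in the tests

The test suite runs the full single-cell recovery at 3,000 cells × 1,500
genes for three seeds (ARI ≥ 0.9, ≥ 8/9 clusters annotated correctly),
the DE null calibration at 5 × 2,000 genes (3 vs 3), the k-selection rule
over 20 seeds (≥ 16 must yield global 3 / second 7), the Voronoi oracle
at 512 × 512 with 50 nuclei (pixel-exact), and the spatial chain at 200
cells in a 2800 px frame (assignment accuracy ≥ 0.95, cell-type accuracy
≥ 0.85). `scripts/acceptance.py` re-runs the same conditions once from a
single seed. Exact identities (QC oracle, pseudo-bulk conservation, spot
conservation, expansion oracle, BH oracle) are asserted with no
tolerance; conservation of the normalization at 1e-6 relative; stochastic
recoveries at the thresholds above.

## Known limitations

* The DE test is a deliberately simplified NB Wald test; real-data DEG
  counts will differ from reference implementations that shrink
  dispersions and fold changes.
* The jackstraw recomputes a full PCA per permutation round and is meant
  for matrices up to a few thousand cells × a few thousand genes.
* The built-in segmenter assumes roughly circular, well-separated nuclei;
  dense or irregular tissue needs an external mask.
* Mixture recovery by NNLS assumes cluster profiles are linearly
  independent over the chosen gene set; collinear profiles raise an
  explicit error.
* The exact Wilcoxon path enumerates up to 20,000 assignments; beyond
  that the tie-corrected normal approximation is used, which is slightly
  conservative for very small groups just above the cutoff.
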