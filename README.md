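# panethkit

Paneth cells (PCs) are secretory epithelial cells of the small-intestinal
crypts that produce antimicrobial peptides (lysozyme, α-defensins) and
support the stem-cell niche. Although often treated as a homogeneous
population, PCs vary along the proximal–distal axis (duodenum → jejunum →
ileum) and include discrete subtypes such as tuft-cell-like PCs (TC-PC),
goblet-cell-like PCs (GC-PC) and Olfm4⁺ immature progenitors.

`panethkit` is a reusable, tested implementation of the computational
workflow for characterizing these subpopulations from three complementary
data modalities, aimed at computational biologists who want to run, audit
or extend each stage:

* **Single-cell RNA-seq** (`panethkit.sc`) — QC (genes in ≥ 10 cells;
  100–2500 features per cell; mitochondrial fraction ≤ 5%),
  log-normalization to 10,000 counts, 2,000 variable genes, cell-cycle
  regression, PCA (15 PCs, with a jackstraw permutation test for PC
  significance), SNN-Jaccard + Leiden clustering, one-vs-rest marker genes
  under 60% detection / 10% difference gates with exact small-sample
  Wilcoxon tests, and signature-based subtype annotation.
* **Regional bulk RNA-seq** (`panethkit.bulk`) — a self-contained
  negative-binomial Wald test (median-of-ratios size factors, moment
  dispersion with a trended floor, BH correction at 5% FDR), DEG union
  across pairwise region contrasts, and k-means grouping of regional
  expression profiles with gap/silhouette/elbow screening of k ∈ [2, 15],
  including the second-local-optimum rule that prefers k = 7 over the
  global optimum at the number of regions.
* **Bulk ↔ single-cell integration** (`panethkit.integrate`) —
  cluster-level pseudo-bulk aggregation, correlation of cluster profiles
  with region profiles on the DEG intersect (log1p CPM), NNLS mixture
  weights, and a margin rule that assigns each cluster a region, a joint
  label (e.g. `jejunum/ileum`) or `uniform`.
* **Spatial molecular cartography** (`panethkit.spatial`) — image
  stitching and background subtraction, classical nuclei segmentation at a
  30 px expected diameter (external masks pluggable), **Voronoi expansion**
  of nuclei by 30 px with an exact smaller-label tie rule, transcript-spot
  assignment with retention accounting, co-location permutation tests,
  replicate merging with a batch-mixing check, and mapping cluster
  identities back onto the image.
* **Probe-panel design** (`panethkit.probes`) — transcript-length and
  expected-signal filters plus greedy panel selection under a probe-count
  (≤ 100) and total-signal cap.
* **Synthetic ground truth** (`panethkit.synthetic`) — generators for all
  three modalities with planted subtypes, regional mixtures and crypt-like
  images, so every stage is testable against known truth.

## The statistics at the core

For a gene *g* with normalized counts *y* (counts divided by
median-of-ratios size factors *s<sub>j</sub>*), the DE test models
*k<sub>gj</sub>* ~ NB(μ, α) with Var = μ + αμ². The Wald statistic is

&nbsp;&nbsp;&nbsp;&nbsp;z = log₂FC / SE, &nbsp; SE² = [Σ<sub>j∈A</sub>(1/s<sub>j</sub>)/(n<sub>A</sub>²μ̂<sub>A</sub>) + α̂/n<sub>A</sub> + (same for B)] / ln²2

with α̂ the per-gene moment estimate floored at the median dispersion of
similarly expressed genes. Voronoi expansion assigns each background pixel
within radius *r* of any nucleus the label of its nearest labeled pixel
(exact Euclidean, integer squared distances; ties to the smaller label).
The k-selection rule ranks the local optima of mean silhouette over
k ∈ [2, 15] and returns the n-th best — the gap statistic
Gap(k) = ⟨log W\*ₖ⟩ − log Wₖ (uniform references in the PCA-aligned box)
breaks ties.

## Worked example

```python
from panethkit import PipelineConfig
from panethkit.synthetic import generate_sc_counts
from panethkit.sc import run_sc_pipeline
from sklearn.metrics import adjusted_rand_score

m, truth = generate_sc_counts(n_cells=3000, n_genes=1500, n_subtypes=9, seed=1)
cfg = PipelineConfig(rng_seed=1)
res = run_sc_pipeline(m, cfg, signatures=truth.annotation_signatures,
                      s_genes=truth.s_genes, g2m_genes=truth.g2m_genes,
                      mito_genes=truth.mito_genes)
print("cells kept:", res.qc_report.n_cells_out)
print("clusters:", res.labeling.n_clusters)
print("ARI vs truth:", adjusted_rand_score(
    truth.labels_for(res.filtered.row_ids), res.labeling.labels))
print(res.labeling.annotation)
```

prints

```
cells kept: 2800
clusters: 9
ARI vs truth: 1.0
{0: 'mature_PC', 1: 'mature_PC', 2: 'immature_PC', 3: 'mature_PC',
 4: 'mito_low', 5: 'TC_PC', 6: 'mature_PC', 7: 'GC_PC', 8: 'mito_high'}
```

200 of the 3,000 simulated cells were planted to violate a QC rule or to
carry a high mitochondrial load, and the pipeline removes them; the nine
Leiden clusters coincide exactly with the nine planted subtypes (adjusted
Rand index 1.0), and each cluster receives its planted annotation — four
mature PC clusters, the tuft-like and goblet-like subtypes, the immature
progenitors, and the mitochondria-high/-low states.

The same truth object feeds the other modalities: `generate_region_bulk`
mixes the subtype profiles into duodenum/jejunum/ileum samples (dominant
subtype weight 0.7), and `generate_cartography_sample` renders a
crypt-like nuclei image with perinuclear transcript clouds in which only
~20% of spots fall inside nuclei — rising to ~41% of transcripts assigned
after the 30 px Voronoi expansion.

A console entry point `panethkit` exposes the same stages on files:
`panethkit simulate | sc | bulk | integrate | cartography | probes`
(each subcommand logs versions, seed and configuration).

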