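"""Single-cell pipeline: QC, normalization, regression, clustering, markers."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from panethkit import PipelineConfig
from panethkit.core import ConfigError, CountMatrix, ValidationError
from panethkit.sc import (
    ClusterLabeling,
    annotate_clusters,
    cluster_cells,
    find_markers,
    flag_doublets,
    jackstraw_select_pcs,
    lognormalize,
    qc_filter,
    run_pca,
    scale_matrix,
    score_and_regress_cell_cycle,
    select_variable_genes,
    wilcoxon_rank_sum,
)
from panethkit.synthetic import generate_sc_counts

from conftest import qc_oracle, random_count_matrix


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


class TestQcFilter:
    def test_cell_over_mito_cutoff_removed(self):
        cfg = PipelineConfig(sc_min_cells=1, sc_min_features=1)
        genes = ["mt-1"] + [f"g{i}" for i in range(9)]
        counts = np.ones((3, 10), dtype=int) * 10
        counts[1, 0] = 6  # cell 1: 6 mito / 96 total = 0.0625 > 0.05
        counts[0, 0] = 0
        counts[2, 0] = 0
        m = CountMatrix(counts, ["a", "b", "c"], genes)
        out, report = qc_filter(m, cfg)
        assert out.row_ids == ["a", "c"]
        assert report.n_cells_removed_mito == 1
        assert report.per_cell.loc["b", "mito_fraction"] == pytest.approx(6 / 96)

    def test_clean_matrix_passes_identity(self):
        cfg = PipelineConfig(sc_min_cells=1, sc_min_features=1)
        m = random_count_matrix(np.random.default_rng(1), 20, 30, n_mito=0)
        out, report = qc_filter(m, cfg)
        assert out.shape == m.shape
        assert report.n_genes_removed == 0

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        """Property: implementation equals the triple-scan oracle."""
        cfg = PipelineConfig(sc_min_cells=3, sc_min_features=4,
                             sc_max_features=25, sc_max_mito_fraction=0.2)
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = random_count_matrix(rng, int(rng.integers(10, 60)),
                                    int(rng.integers(10, 40)))
            cells, genes, vals = qc_oracle(m, cfg)
            try:
                out, _ = qc_filter(m, cfg)
            except Exception:
                assert len(cells) == 0 or len(genes) == 0
                continue
            assert out.row_ids == cells
            assert out.col_ids == genes
            np.testing.assert_array_equal(out.to_dense(), vals)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


class TestLognormalize:
    def test_single_gene_closed_form(self):
        m = CountMatrix([[5]], ["c"], ["g"])
        out = lognormalize(m, 10000)
        assert out.to_dense()[0, 0] == pytest.approx(np.log(1 + 10000))

    def test_expm1_sums_to_scale_total(self, rng):
        m = random_count_matrix(rng, 15, 25)
        keep = m.to_dense().sum(axis=1) > 0
        m = m.subset(rows=keep)
        out = lognormalize(m, 10000)
        sums = np.expm1(out.to_dense()).sum(axis=1)
        np.testing.assert_allclose(sums, 10000, rtol=1e-6)

    def test_doubling_counts_is_invariant(self):
        counts = np.array([[3, 7, 0], [1, 1, 8]])
        m1 = CountMatrix(counts, ["a", "b"], ["x", "y", "z"])
        m2 = CountMatrix(counts * 2, ["a", "b"], ["x", "y", "z"])
        np.testing.assert_allclose(lognormalize(m1).to_dense(),
                                   lognormalize(m2).to_dense())

    def test_zero_total_cell_rejected(self):
        m = CountMatrix([[0, 0], [1, 2]], ["a", "b"], ["x", "y"])
        with pytest.raises(ValidationError, match="qc_filter"):
            lognormalize(m)


class TestVariableGenes:
    def test_planted_markers_all_selected(self):
        m, t = generate_sc_counts(n_cells=800, n_genes=500, seed=3)
        markers = [g for ms in t.marker_sets.values() for g in ms]
        selected = set(select_variable_genes(m, 150))
        assert set(markers) <= selected

    def test_constant_gene_never_beats_varying(self, rng):
        counts = rng.integers(1, 30, size=(40, 10))
        counts[:, 0] = 5  # constant gene first
        m = CountMatrix(counts, [f"c{i}" for i in range(40)],
                        [f"g{i}" for i in range(10)])
        assert select_variable_genes(m, 9)[-1] != "g0"

    def test_n_larger_than_genes_returns_all(self, rng):
        m = random_count_matrix(rng, 10, 8)
        assert len(select_variable_genes(m, 100)) == 8

    def test_nonpositive_n_rejected(self, rng):
        with pytest.raises(ConfigError):
            select_variable_genes(random_count_matrix(rng, 5, 5), 0)


# ---------------------------------------------------------------------------
# Cell cycle
# ---------------------------------------------------------------------------


class TestCellCycle:
    def test_no_cycle_program_leaves_data_unchanged(self):
        # homogeneous counts: scores are pure noise, so the residuals
        # should match a plain z-scored matrix almost exactly
        rng = np.random.default_rng(5)
        mu = rng.lognormal(1.0, 0.5, size=300)
        counts = rng.poisson(np.tile(mu, (500, 1)))
        genes = [f"g{i}" for i in range(300)]
        m = CountMatrix(counts, [f"c{i}" for i in range(500)], genes)
        s_genes, g2m_genes = genes[:10], genes[10:20]
        logn = lognormalize(m)
        scaled_plain = scale_matrix(logn).to_dense()
        regressed, _ = score_and_regress_cell_cycle(logn, s_genes, g2m_genes)
        R = regressed.to_dense()
        cors = [np.corrcoef(R[:, j], scaled_plain[:, j])[0, 1]
                for j, g in enumerate(logn.col_ids)
                if g not in set(s_genes + g2m_genes)
                and scaled_plain[:, j].std() > 0]
        assert np.nanmedian(cors) > 0.99

    def test_cycle_signal_removed_from_cycle_genes(self):
        m, t = generate_sc_counts(n_cells=800, n_genes=400, seed=6,
                                  cycling_fraction=0.3)
        logn = lognormalize(m)
        regressed, scores = score_and_regress_cell_cycle(logn, t.s_genes,
                                                         t.g2m_genes)
        R = regressed.to_dense()
        cols = [logn.col_ids.index(g) for g in t.s_genes]
        for c in cols:
            r = np.corrcoef(scores["S"], R[:, c])[0, 1]
            assert abs(r) < 0.05

    def test_empty_g2m_set_degenerates_gracefully(self):
        m, t = generate_sc_counts(n_cells=200, n_genes=400, seed=7)
        logn = lognormalize(m)
        regressed, scores = score_and_regress_cell_cycle(logn, t.s_genes, [])
        assert "G2M" not in scores.columns
        assert regressed.layer_tag == "scaled"

    def test_all_gene_sets_absent_rejected(self):
        m, _ = generate_sc_counts(n_cells=100, n_genes=400, seed=8)
        with pytest.raises(ValidationError):
            score_and_regress_cell_cycle(lognormalize(m), ["nope1"], ["nope2"])


# ---------------------------------------------------------------------------
# PCA / jackstraw
# ---------------------------------------------------------------------------


def _toy_scaled(rng, n=80, g=30, planted_dims=0, strength=6.0):
    X = rng.normal(size=(n, g))
    for d in range(planted_dims):
        direction = rng.normal(size=g)
        direction /= np.linalg.norm(direction)
        X += strength * rng.normal(size=(n, 1)) * direction[None, :]
    Z = (X - X.mean(0)) / X.std(0)
    return CountMatrix(Z, [f"c{i}" for i in range(n)],
                       [f"g{i}" for i in range(g)], "scaled", validate=False)


class TestPca:
    def test_rank_one_data_explained_by_first_pc(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(50, 1))
        v = rng.normal(size=(1, 20))
        m = CountMatrix(u @ v, [f"c{i}" for i in range(50)],
                        [f"g{i}" for i in range(20)], "scaled",
                        validate=False)
        _, evr = run_pca(m, 5)
        assert evr[0] > 0.999
        assert np.all(np.diff(evr) <= 1e-12)

    def test_two_cluster_structure_better_than_random_axes(self):
        rng = np.random.default_rng(1)
        centers = np.zeros((100, 30))
        centers[50:, :3] = 6.0
        X = centers + rng.normal(size=(100, 30))
        m = CountMatrix((X - X.mean(0)) / X.std(0),
                        [f"c{i}" for i in range(100)],
                        [f"g{i}" for i in range(30)], "scaled",
                        validate=False)
        emb, _ = run_pca(m, 5)
        labels = (np.arange(100) >= 50).astype(int)
        sep_pca = abs(emb[labels == 1, 0].mean() - emb[labels == 0, 0].mean())
        rand_axis = rng.normal(size=30)
        proj = X @ rand_axis / np.linalg.norm(rand_axis)
        sep_rand = abs(proj[labels == 1].mean() - proj[labels == 0].mean())
        assert sep_pca > sep_rand

    def test_sign_flip_leaves_clustering_unchanged(self):
        rng = np.random.default_rng(2)
        emb = np.vstack([rng.normal(0, 1, size=(60, 5)),
                         rng.normal(6, 1, size=(60, 5))])
        l1 = cluster_cells(emb, knn_k=10, seed=0)
        l2 = cluster_cells(emb * np.array([-1, 1, -1, 1, 1]), knn_k=10, seed=0)
        assert adjusted_rand_score(l1.labels, l2.labels) == 1.0

    def test_n_pcs_at_rank_rejected(self):
        rng = np.random.default_rng(3)
        m = _toy_scaled(rng, n=10, g=5)
        with pytest.raises(ConfigError):
            run_pca(m, 5)


class TestJackstraw:
    def test_pure_noise_yields_few_significant_pcs(self):
        sig_counts = []
        for seed in range(10):
            m = _toy_scaled(np.random.default_rng(seed), n=60, g=40)
            sig = jackstraw_select_pcs(m, n_pcs=10, n_perm=30, seed=seed)
            sig_counts.append(len(sig))
        assert np.mean(sig_counts) <= 0.05 * 10 + 0.5

    def test_three_planted_dimensions_recovered(self):
        hits = []
        for seed in range(5):
            m = _toy_scaled(np.random.default_rng(100 + seed), n=150, g=60,
                            planted_dims=3)
            sig = jackstraw_select_pcs(m, n_pcs=8, n_perm=40, seed=seed)
            hits.append(len(sig))
        assert np.median(hits) in (2, 3, 4)

    def test_same_seed_identical(self):
        m = _toy_scaled(np.random.default_rng(9), n=60, g=40, planted_dims=2)
        a = jackstraw_select_pcs(m, n_pcs=6, n_perm=25, seed=3)
        b = jackstraw_select_pcs(m, n_pcs=6, n_perm=25, seed=3)
        assert a == b

    def test_bad_frac_genes_rejected(self):
        m = _toy_scaled(np.random.default_rng(9), n=30, g=20)
        with pytest.raises(ConfigError):
            jackstraw_select_pcs(m, frac_genes=0.9)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


class TestClusterCells:
    def test_two_separated_blobs_fully_recovered(self):
        rng = np.random.default_rng(4)
        emb = np.vstack([rng.normal(0, 1, size=(80, 4)),
                         rng.normal(8, 1, size=(80, 4))])
        truth = np.repeat([0, 1], 80)
        labeling = cluster_cells(emb, knn_k=15, seed=0)
        assert adjusted_rand_score(truth, labeling.labels) == 1.0

    def test_duplicating_cells_preserves_partition(self):
        rng = np.random.default_rng(5)
        emb = np.vstack([rng.normal(0, 1, size=(100, 4)),
                         rng.normal(8, 1, size=(100, 4))])
        base = cluster_cells(emb, knn_k=20, resolution=0.5, seed=0)
        # same effective neighborhood radius: k scales with point density
        doubled = cluster_cells(np.vstack([emb, emb]), knn_k=40,
                                resolution=0.5, seed=0)
        assert adjusted_rand_score(base.labels,
                                   doubled.labels[: len(emb)]) == 1.0

    def test_labels_sorted_by_cluster_size(self):
        rng = np.random.default_rng(6)
        emb = np.vstack([rng.normal(0, 1, size=(100, 3)),
                         rng.normal(9, 1, size=(30, 3))])
        labeling = cluster_cells(emb, knn_k=10, seed=0)
        sizes = labeling.cluster_sizes()
        assert list(sizes.values) == sorted(sizes.values, reverse=True)

    def test_knn_k_too_large_rejected(self):
        with pytest.raises(ConfigError):
            cluster_cells(np.zeros((5, 2)), knn_k=5)


# ---------------------------------------------------------------------------
# Wilcoxon and markers
# ---------------------------------------------------------------------------


class TestWilcoxon:
    def test_exact_three_vs_three_extreme_separation(self):
        """Complete separation of 3 vs 3 has exact two-sided p = 2/20."""
        p = wilcoxon_rank_sum(np.array([2.0, 2.0, 2.0]),
                              np.array([0.0, 0.0, 0.0]))
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 3), (5, 4)])
    def test_matches_exact_mannwhitney_on_tie_free_data(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(20):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                          method="exact").pvalue
            assert wilcoxon_rank_sum(x, y) == pytest.approx(expected)


class TestFindMarkers:
    def _two_cluster_fixture(self, rng, n_per=20, n_genes=12):
        counts = rng.integers(0, 6, size=(2 * n_per, n_genes))
        counts[:n_per, 0] += 30  # strong marker of cluster 0
        m = CountMatrix(counts, [f"c{i}" for i in range(2 * n_per)],
                        [f"g{i}" for i in range(n_genes)])
        labels = ClusterLabeling(m.row_ids, np.repeat([0, 1], n_per))
        return lognormalize(m), labels

    def test_detection_gate_excludes_low_pct_genes(self, cfg):
        # gene detected in 55% of cluster 0 and 50% of cluster 1: both
        # gates fail (max pct < 0.60 and diff < 0.10) -> never tested
        logn_vals = np.zeros((40, 2))
        logn_vals[:11, 0] = 1.0      # 55% of cluster 0
        logn_vals[20:30, 0] = 1.0    # 50% of cluster 1
        logn_vals[:, 1] = 1.0        # keep a testable gene in the table
        logn_vals[20:, 1] = 0.0
        m = CountMatrix(logn_vals, [f"c{i}" for i in range(40)],
                        ["gated_out", "real"], "lognorm", validate=False)
        labels = ClusterLabeling(m.row_ids, np.repeat([0, 1], 20))
        table = find_markers(m, labels, cfg)
        assert "gated_out" not in set(table["gene"])
        assert "real" in set(table["gene"])

    def test_planted_marker_recovered_with_low_q(self, cfg):
        logn, labels = self._two_cluster_fixture(np.random.default_rng(1))
        table = find_markers(logn, labels, cfg)
        row = table[(table.cluster == 0) & (table.gene == "g0")]
        assert len(row) == 1
        assert row.iloc[0]["q"] < 0.05 and row.iloc[0]["direction"] == "up"

    def test_label_swap_equivariance(self, cfg):
        logn, labels = self._two_cluster_fixture(np.random.default_rng(2))
        swapped = ClusterLabeling(labels.cell_ids, 1 - labels.labels)
        t1 = find_markers(logn, labels, cfg)
        t2 = find_markers(logn, swapped, cfg)
        t2 = t2.assign(cluster=1 - t2.cluster)
        key = ["cluster", "gene"]
        merged = t1.merge(t2, on=key, suffixes=("_a", "_b"))
        assert len(merged) == len(t1)
        np.testing.assert_allclose(merged["p_a"], merged["p_b"])

    def test_single_cluster_rejected(self, cfg):
        logn, _ = self._two_cluster_fixture(np.random.default_rng(3))
        labels = ClusterLabeling(logn.row_ids,
                                 np.zeros(logn.shape[0], dtype=int))
        with pytest.raises(ValidationError):
            find_markers(logn, labels, cfg)


class TestAnnotation:
    def test_forced_argmax_assigns_tuft_label(self, cfg):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 4, size=(40, 10))
        counts[:20, 0:2] += 40  # cluster 0 expresses the tuft signature
        genes = ["Dclk1", "St18"] + [f"g{i}" for i in range(8)]
        m = lognormalize(CountMatrix(counts, [f"c{i}" for i in range(40)],
                                     genes))
        labels = ClusterLabeling(m.row_ids, np.repeat([0, 1], 20))
        out = annotate_clusters(None, m, labels,
                                {"TC_PC": ["Dclk1", "St18"],
                                 "GC_PC": ["g5"]})
        assert out.annotation[0] == "TC_PC"

    def test_identical_clusters_fall_back_to_mature(self, cfg):
        counts = np.full((30, 6), 5)
        m = lognormalize(CountMatrix(counts, [f"c{i}" for i in range(30)],
                                     [f"g{i}" for i in range(6)]))
        labels = ClusterLabeling(m.row_ids, np.repeat([0, 1, 2], 10))
        out = annotate_clusters(None, m, labels, {"TC_PC": ["g0"],
                                                  "GC_PC": ["g1"]})
        assert set(out.annotation.values()) == {"mature_PC"}

    def test_no_signature_gene_present_rejected(self, cfg):
        m = lognormalize(CountMatrix(np.full((10, 3), 4),
                                     [f"c{i}" for i in range(10)],
                                     ["a", "b", "c"]))
        labels = ClusterLabeling(m.row_ids, np.repeat([0, 1], 5))
        with pytest.raises(ValidationError):
            annotate_clusters(None, m, labels, {"TC_PC": ["zz"]})


class TestDoublets:
    def test_high_count_multi_signature_cell_flagged(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 5, size=(200, 10))
        counts[0, :4] = 60  # huge library, hot on both signatures
        m = CountMatrix(counts, [f"c{i}" for i in range(200)],
                        [f"g{i}" for i in range(10)])
        logn = lognormalize(m)
        flags = flag_doublets(m, logn, {"a": ["g0", "g1"], "b": ["g2", "g3"]})
        assert flags[0]
        assert flags.sum() <= 2
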