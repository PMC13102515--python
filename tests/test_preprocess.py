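"""Normalization, PCA, SNN graph, Louvain clustering, markers, replicates."""

import math

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from stregnet.io import CountMatrix
from stregnet.preprocess import (
    build_knn_graph,
    find_markers,
    louvain_cluster,
    normalize_log_cpm,
    qc_filter,
    replicate_consistency,
    run_pca,
    sweep_resolution,
)


def make_matrix(counts, prefix="b"):
    counts = np.asarray(counts)
    return CountMatrix(
        sp.csr_matrix(counts),
        [f"{prefix}{i}" for i in range(counts.shape[0])],
        [f"g{j}" for j in range(counts.shape[1])],
    )


class TestQC:
    def test_zero_thresholds_are_identity(self):
        m = make_matrix([[1, 0], [0, 2]])
        out = qc_filter(m, 0, 0)
        assert np.array_equal(out.dense(), m.dense())

    def test_undetected_gene_removed(self):
        m = make_matrix([[1, 0, 3], [2, 0, 1]])
        out = qc_filter(m, 0, 1)
        assert out.gene_ids == ["g0", "g2"]

    def test_low_count_spot_removed(self):
        m = make_matrix([[10, 0], [3, 0]])
        out = qc_filter(m, 5, 0)
        assert out.barcodes == ["b0"]

    def test_all_spots_removed_is_an_error(self):
        with pytest.raises(ValueError, match="empty matrix after QC"):
            qc_filter(make_matrix([[1, 0]]), 100, 0)


class TestNormalize:
    def test_closed_form_value(self):
        m = make_matrix([[1, 1]])
        norm = normalize_log_cpm(m, scale_factor=1e4)
        np.testing.assert_allclose(norm.values, math.log(5001.0))

    def test_all_zero_spot_stays_zero_with_warning(self, caplog):
        m = make_matrix([[0, 0], [1, 1]])
        with caplog.at_level("WARNING"):
            norm = normalize_log_cpm(m)
        np.testing.assert_allclose(norm.values[0], 0.0)

    def test_scale_invariance_per_spot(self):
        m1 = make_matrix([[2, 4, 6]])
        m2 = make_matrix([[20, 40, 60]])
        np.testing.assert_allclose(
            normalize_log_cpm(m1).values, normalize_log_cpm(m2).values
        )

    def test_expm1_row_sums_equal_scale_factor(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.integers(0, 20, size=(5, 30)))
        norm = normalize_log_cpm(m, 1e4)
        np.testing.assert_allclose(np.expm1(norm.values).sum(axis=1), 1e4, rtol=1e-9)


class TestPCA:
    def _norm(self, values):
        from stregnet.preprocess import NormalizedMatrix

        values = np.asarray(values, dtype=float)
        return NormalizedMatrix(
            values,
            [f"b{i}" for i in range(values.shape[0])],
            [f"g{j}" for j in range(values.shape[1])],
            1e4,
        )

    def test_single_axis_of_variation(self):
        norm = self._norm([[0, 5], [1, 5], [2, 5]])
        emb = run_pca(norm, n_pcs=2, scale_genes=False)
        assert np.var(emb[:, 0]) > 0
        np.testing.assert_allclose(emb[:, 1], 0.0, atol=1e-12)

    def test_diagonal_points_hand_eigendecomposition(self):
        norm = self._norm([[0, 0], [1, 1], [2, 2]])
        emb = run_pca(norm, n_pcs=2, scale_genes=False)
        # PC1 direction is (1,1)/sqrt(2): scores are +-sqrt(2), 0
        np.testing.assert_allclose(
            np.sort(emb[:, 0]), [-math.sqrt(2), 0.0, math.sqrt(2)], atol=1e-12
        )
        np.testing.assert_allclose(emb[:, 1], 0.0, atol=1e-12)

    def test_explained_variance_nonincreasing(self):
        rng = np.random.default_rng(1)
        norm = self._norm(rng.normal(size=(40, 10)))
        emb = run_pca(norm, n_pcs=5)
        variances = emb.var(axis=0, ddof=1)
        assert np.all(np.diff(variances) <= 1e-9)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            run_pca(self._norm(np.zeros((3, 2))), n_pcs=5)


class TestKnnGraph:
    def test_separated_clouds_have_no_cross_edges(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(20, 2))
        b = rng.normal(50, 0.1, size=(20, 2))
        graph = build_knn_graph(np.vstack([a, b]), k=5)
        for i, j in graph.edges:
            assert (i < 20) == (j < 20)

    def test_full_k_gives_complete_graph(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 2))
        graph = build_knn_graph(pts, k=7)
        assert graph.number_of_edges() == 8 * 7 // 2

    def test_weights_are_jaccard_in_unit_interval(self):
        rng = np.random.default_rng(2)
        graph = build_knn_graph(rng.normal(size=(30, 3)), k=5)
        weights = [d["weight"] for _, _, d in graph.edges(data=True)]
        assert weights and all(0 < w <= 1 for w in weights)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            build_knn_graph(np.zeros((5, 2)), k=0)
        with pytest.raises(ValueError):
            build_knn_graph(np.zeros((5, 2)), k=5)


class TestLouvain:
    def test_two_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        nx.set_edge_attributes(g, 1.0, "weight")
        res = louvain_cluster(g, [f"b{i}" for i in range(10)], seed=0)
        assert res.n_clusters == 2
        assert len(set(res.labels[:5])) == 1 and len(set(res.labels[5:])) == 1

    def test_deterministic_at_fixed_seed(self):
        rng = np.random.default_rng(3)
        pts = np.vstack(
            [rng.normal(c, 0.5, size=(30, 2)) for c in (0, 10, 20)]
        )
        graph = build_knn_graph(pts, k=6)
        barcodes = [f"b{i}" for i in range(90)]
        r1 = louvain_cluster(graph, barcodes, seed=7)
        r2 = louvain_cluster(graph, barcodes, seed=7)
        assert np.array_equal(r1.labels, r2.labels)

    def test_edgeless_graph_degenerates_to_singletons(self, caplog):
        g = nx.empty_graph(4)
        with caplog.at_level("WARNING"):
            res = louvain_cluster(g, list("abcd"))
        assert res.n_clusters == 4

    def test_labels_ordered_by_cluster_size(self):
        g = nx.disjoint_union(nx.complete_graph(7), nx.complete_graph(3))
        nx.set_edge_attributes(g, 1.0, "weight")
        res = louvain_cluster(g, [f"b{i}" for i in range(10)], seed=0)
        assert (res.labels[:7] == 0).all() and (res.labels[7:] == 1).all()

    def test_sweep_reaches_target_count(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(c, 0.5, size=(40, 2)) for c in (0, 10, 20)])
        graph = build_knn_graph(pts, k=8)
        res = sweep_resolution(graph, [f"b{i}" for i in range(120)], 3, seed=0)
        assert res.n_clusters == 3


class TestMarkers:
    def _norm_with_clusters(self, values, labels):
        from stregnet.preprocess import ClusterResult, NormalizedMatrix

        values = np.asarray(values, dtype=float)
        norm = NormalizedMatrix(
            values,
            [f"b{i}" for i in range(values.shape[0])],
            [f"g{j}" for j in range(values.shape[1])],
            1e4,
        )
        clusters = ClusterResult(np.asarray(labels), norm.barcodes, 1.0)
        return norm, clusters

    def test_perfect_marker_tops_its_cluster(self):
        values = np.zeros((8, 2))
        values[:4, 0] = 10.0  # gene g0 exclusive to cluster 0
        values[:, 1] = 1.0
        norm, clusters = self._norm_with_clusters(values, [0, 0, 0, 0, 1, 1, 1, 1])
        table = find_markers(norm, clusters)
        top = table[table["cluster"] == 0].iloc[0]
        assert top["gene"] == "g0"
        assert top["frac_in"] == 1.0 and top["frac_out"] == 0.0

    def test_identical_distribution_gene_absent(self):
        values = np.ones((8, 1))
        norm, clusters = self._norm_with_clusters(values, [0, 0, 0, 0, 1, 1, 1, 1])
        table = find_markers(norm, clusters)
        assert len(table) == 0  # fails the fold-change filter

    def test_exact_wilcoxon_p_in_table(self):
        # in-cluster (5,6,7) vs rest (1,2,3): exact two-sided p = 2/20
        values = np.array([[5.0], [6.0], [7.0], [1.0], [2.0], [3.0]])
        norm, clusters = self._norm_with_clusters(values, [0, 0, 0, 1, 1, 1])
        table = find_markers(norm, clusters, min_frac_in=0.0, min_log2fc=0.0)
        row = table[(table["cluster"] == 0) & (table["gene"] == "g0")].iloc[0]
        assert row["p"] == pytest.approx(0.1)

    def test_single_cluster_rejected(self):
        values = np.ones((4, 2))
        norm, clusters = self._norm_with_clusters(values, [0, 0, 0, 0])
        with pytest.raises(ValueError):
            find_markers(norm, clusters)


class TestReplicateConsistency:
    def test_duplicated_region_gives_r2_one(self):
        counts = np.array([[5, 1, 9], [5, 1, 9], [2, 8, 3], [2, 8, 3]])
        m = make_matrix(counts)
        # b0/b1 and b2/b3 are copies: mean profiles of {b0,b2} and {b1,b3} coincide
        assert replicate_consistency(m, ["b0", "b2"], ["b1", "b3"]) == pytest.approx(1.0)

    def test_overlapping_regions_rejected(self):
        m = make_matrix([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="disjoint"):
            replicate_consistency(m, ["b0"], ["b0", "b1"])

    def test_cross_domain_r2_below_within_domain(self):
        from stregnet.synthetic import default_screen_spec, simulate_tissue

        spec = default_screen_spec(seed=0)
        matrix, _, _, truth = simulate_tissue(spec)
        rng = np.random.default_rng(0)
        by_domain = {}
        for barcode in matrix.barcodes:
            by_domain.setdefault(truth.domain_of[barcode], []).append(barcode)
        d0 = by_domain[0]
        d1 = by_domain[1]
        half = len(d0) // 2
        within = replicate_consistency(matrix, d0[:half], d0[half : 2 * half])
        across = replicate_consistency(matrix, d0[:half], d1[:half])
        assert across < within
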