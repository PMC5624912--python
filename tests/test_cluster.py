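import numpy as np
import pytest
from hypothesis import given, strategies as st

from gangliotype.cluster import (
    ClusterAssignment,
    UNASSIGNED,
    adjusted_rand_index,
    concordance_report,
    correlation_distance,
    cut_tree,
    log_transform,
    pairwise_pcc,
    run_pca,
    upgma,
)
from gangliotype.io import ExpressionMatrix

from .oracles import contingency_ari, dendrogram_leaf_sets, naive_upgma


def _mat(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values, genes, cells)


def _random_distance(rng, n):
    d = rng.uniform(0.05, 1.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestLogTransform:
    @pytest.mark.parametrize("fpkm,expected", [(0, 0), (1, 1), (255, 8)])
    def test_log2_plus_one(self, fpkm, expected):
        out = log_transform(_mat([[fpkm]]))
        assert out.values[0, 0] == pytest.approx(expected)


class TestPairwisePCC:
    def test_identical_profiles_correlate_perfectly(self):
        mat = _mat([[1, 1, 5], [2, 2, 1], [9, 9, 0]])
        pcc = pairwise_pcc(mat)
        assert pcc.values[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_profiles(self):
        mat = _mat([[1, 3], [2, 2], [3, 1]])
        assert pairwise_pcc(mat).values[0, 1] == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self, rng):
        mat = _mat(rng.gamma(1.0, 10.0, size=(20, 6)))
        pcc = pairwise_pcc(mat)
        X = mat.values
        for i in range(6):
            for j in range(6):
                xi, xj = X[:, i], X[:, j]
                manual = np.mean((xi - xi.mean()) * (xj - xj.mean())) / (
                    xi.std() * xj.std()
                )
                assert abs(pcc.values[i, j] - manual) < 1e-12

    def test_zero_variance_cell_named(self):
        mat = _mat([[1, 4], [1, 5], [1, 6]], cells=["flatcell", "ok"])
        with pytest.raises(ValueError, match="flatcell"):
            pairwise_pcc(mat)

    def test_scale_invariance_of_pcc(self, rng):
        mat = _mat(rng.gamma(1.0, 10.0, size=(15, 4)))
        scaled = mat.values.copy()
        scaled[:, 2] *= 7.5
        pcc_a = pairwise_pcc(mat).values
        pcc_b = pairwise_pcc(_mat(scaled)).values
        np.testing.assert_allclose(pcc_a, pcc_b, atol=1e-12)


class TestUPGMA:
    def test_two_leaves_merge_at_their_distance(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        tree = upgma(d, ["a", "b"])
        assert tree.merges[0, 2] == pytest.approx(0.7)

    def test_matches_exhaustive_oracle_on_random_matrices(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 8))
            d = _random_distance(rng, n)
            tree = upgma(d)
            got = dendrogram_leaf_sets(tree.merges, n)
            expected = naive_upgma(d)
            for (gset, gh), (ea, eb, eh) in zip(got, expected):
                assert gset == ea | eb
                assert gh == pytest.approx(eh, abs=1e-12)

    def test_tie_merges_lexicographically_smallest_pair(self):
        # leaves 0-3 all mutually at distance 0.5: first merge must be (0,1)
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        tree = upgma(d)
        assert (int(tree.merges[0, 0]), int(tree.merges[0, 1])) == (0, 1)

    def test_heights_non_decreasing(self, rng):
        for _ in range(20):
            d = _random_distance(rng, 10)
            heights = upgma(d).merges[:, 2]
            assert np.all(np.diff(heights) >= -1e-12)

    def test_permutation_gives_same_tree_heights(self, rng):
        d = _random_distance(rng, 9)
        ids = [f"c{i}" for i in range(9)]
        perm = rng.permutation(9)
        tree_a = upgma(d, ids)
        tree_b = upgma(d[np.ix_(perm, perm)], [ids[i] for i in perm])
        np.testing.assert_allclose(
            np.sort(tree_a.merges[:, 2]), np.sort(tree_b.merges[:, 2]), atol=1e-12
        )
        sets_a = {frozenset(tree_a.leaf_ids[i] for i in s)
                  for s, _ in dendrogram_leaf_sets(tree_a.merges, 9)}
        sets_b = {frozenset(tree_b.leaf_ids[i] for i in s)
                  for s, _ in dendrogram_leaf_sets(tree_b.merges, 9)}
        assert sets_a == sets_b

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            upgma(d)

    def test_newick_serialization_contains_all_leaves(self):
        d = _random_distance(np.random.default_rng(0), 5)
        tree = upgma(d, list("abcde"))
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for leaf in "abcde":
            assert leaf in nwk


class TestCutTree:
    def test_two_block_distance_structure_splits_cleanly(self):
        # two tight blocks far apart
        d = np.full((6, 6), 1.0)
        d[:3, :3] = 0.1
        d[3:, 3:] = 0.1
        np.fill_diagonal(d, 0.0)
        assign = cut_tree(upgma(d), k=2)
        assert set(assign.members("C1")) in ({"0", "1", "2"}, {"3", "4", "5"})
        assert len(assign.sizes()) == 2

    def test_k_equals_leaves_gives_singletons(self):
        d = _random_distance(np.random.default_rng(3), 5)
        assign = cut_tree(upgma(d), k=5)
        assert sorted(assign.sizes().values()) == [1] * 5

    def test_k_above_leaf_count_rejected(self):
        d = _random_distance(np.random.default_rng(3), 4)
        with pytest.raises(ValueError):
            cut_tree(upgma(d), k=5)

    def test_min_cluster_size_sends_stragglers_to_unassigned(self):
        # two blocks of 4 plus one distant singleton leaf
        d = np.full((9, 9), 1.0)
        d[:4, :4] = 0.1
        d[4:8, 4:8] = 0.1
        d[8, :] = d[:, 8] = 2.0
        np.fill_diagonal(d, 0.0)
        assign = cut_tree(upgma(d), k=2, min_cluster_size=3)
        assert assign.labels["8"] == UNASSIGNED
        assert sorted(assign.sizes().values()) == [1, 4, 4]

    def test_clusters_named_by_decreasing_size(self):
        d = np.full((5, 5), 1.0)
        d[:3, :3] = 0.1
        d[3:, 3:] = 0.1
        np.fill_diagonal(d, 0.0)
        assign = cut_tree(upgma(d), k=2)
        assert len(assign.members("C1")) == 3
        assert len(assign.members("C2")) == 2


class TestARI:
    def test_relabeling_is_identity(self):
        a = ClusterAssignment({"c1": "x", "c2": "x", "c3": "y"})
        b = ClusterAssignment({"c1": "T1", "c2": "T1", "c3": "T2"})
        assert adjusted_rand_index(a, b) == pytest.approx(1.0)

    def test_crossed_pairs_give_minus_half(self):
        a = ClusterAssignment(dict(zip("abcd", ["1", "1", "2", "2"])))
        b = ClusterAssignment(dict(zip("abcd", ["1", "2", "1", "2"])))
        assert adjusted_rand_index(a, b) == pytest.approx(-0.5)
        assert contingency_ari(["1", "1", "2", "2"], ["1", "2", "1", "2"]) == \
            pytest.approx(-0.5)

    def test_singletons_vs_one_block_is_zero(self):
        cells = [f"c{i}" for i in range(6)]
        a = ClusterAssignment({c: c for c in cells})
        b = ClusterAssignment({c: "all" for c in cells})
        expected = contingency_ari(cells, ["all"] * 6)
        assert adjusted_rand_index(a, b) == pytest.approx(expected) == 0.0

    def test_matches_contingency_oracle_on_random_partitions(self, rng):
        cells = [f"c{i}" for i in range(40)]
        for _ in range(25):
            la = [str(x) for x in rng.integers(0, 4, 40)]
            lb = [str(x) for x in rng.integers(0, 3, 40)]
            a = ClusterAssignment(dict(zip(cells, la)))
            b = ClusterAssignment(dict(zip(cells, lb)))
            assert adjusted_rand_index(a, b) == pytest.approx(
                contingency_ari(la, lb), abs=1e-12
            )

    def test_unassigned_cells_excluded_pairwise(self):
        a = ClusterAssignment({"c1": "x", "c2": "x", "c3": UNASSIGNED, "c4": "y"})
        b = ClusterAssignment({"c1": "1", "c2": "1", "c3": "2", "c4": "2"})
        assert adjusted_rand_index(a, b) == pytest.approx(1.0)

    def test_disjoint_cell_sets_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index(
                ClusterAssignment({"a": "x"}), ClusterAssignment({"b": "y"})
            )


class TestPCA:
    def test_single_varying_gene_captures_all_variance(self):
        values = np.ones((5, 6))
        values[2] = [1, 2, 3, 4, 5, 6]
        res = run_pca(_mat(values), n_components=2, log=False)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_gene_order_permutation_leaves_scores_unchanged(self, rng):
        mat = _mat(rng.gamma(1.0, 20.0, size=(30, 8)))
        res_a = run_pca(mat, n_components=3)
        perm = list(rng.permutation(mat.gene_ids))
        res_b = run_pca(mat.subset(genes=perm), n_components=3)
        np.testing.assert_allclose(res_a.scores, res_b.scores, atol=1e-10)

    def test_full_reconstruction_recovers_centered_data(self, rng):
        mat = _mat(rng.gamma(1.0, 20.0, size=(12, 7)))
        res = run_pca(mat, n_components=7, log=False)
        X = mat.values.T
        centered = X - X.mean(axis=0)
        reconstructed = res.scores @ res.loadings.T
        np.testing.assert_allclose(reconstructed, centered, atol=1e-8)

    def test_component_count_capped_by_dimensions(self):
        with pytest.raises(ValueError):
            run_pca(_mat(np.ones((3, 2)) + np.eye(3, 2)), n_components=5)

    def test_sign_convention_largest_loading_positive(self, rng):
        res = run_pca(_mat(rng.gamma(1.0, 20.0, size=(20, 6))), n_components=2)
        for c in range(2):
            top = np.argmax(np.abs(res.loadings[:, c]))
            assert res.loadings[top, c] > 0


class TestConcordance:
    def test_two_block_data_agrees_between_hca_and_pca(self, rng):
        # 2 planted blocks in expression space
        base = rng.gamma(1.0, 5.0, size=(40, 12))
        base[:20, :6] *= 30
        base[20:, 6:] *= 30
        mat = _mat(base)
        dist, ids = correlation_distance(mat, None)
        assign = cut_tree(upgma(dist, ids), k=2)
        pca = run_pca(mat, n_components=2)
        rep = concordance_report(assign, pca, k=2)
        assert rep["ari"] == pytest.approx(1.0)

    def test_single_cluster_reports_nan_with_warning(self, rng):
        mat = _mat(rng.gamma(1.0, 5.0, size=(15, 6)))
        assign = ClusterAssignment({c: "all" for c in mat.cell_ids})
        pca = run_pca(mat, n_components=2)
        with pytest.warns(UserWarning, match="undefined"):
            rep = concordance_report(assign, pca, k=1)
        assert np.isnan(rep["ari"])

    def test_shuffled_labels_score_near_zero(self, small_fit, rng):
        res, truth = small_fit
        labels = list(res.level1_assignment.labels.values())
        cells = list(res.level1_assignment.labels)
        aris = []
        for _ in range(100):
            shuffled = ClusterAssignment(
                dict(zip(cells, rng.permutation(labels)))
            )
            aris.append(adjusted_rand_index(res.level1_assignment, shuffled))
        assert np.max(np.abs(aris)) < 0.2
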