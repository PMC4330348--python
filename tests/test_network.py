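import numpy as np
import pandas as pd
import pytest

from silacnet import (
    AdjacencyMatrix,
    CorrelationMatrix,
    Dendrogram,
    TOMatrix,
    cluster_dendrogram,
    dynamic_tree_cut,
    impute_zero,
    pairwise_correlation,
    pick_soft_threshold,
    scale_free_fit,
    signed_adjacency,
    topological_overlap,
)
from silacnet.network import GREY

from conftest import random_ratio_matrix


def _imputed(matrix):
    return impute_zero(matrix)


class TestPairwiseCorrelation:
    def test_identical_rows(self, design):
        matrix = random_ratio_matrix(design, 3, seed=0)
        matrix.values.iloc[1] = matrix.values.iloc[0]
        cor = pairwise_correlation(_imputed(matrix))
        assert cor.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_rows(self, design):
        matrix = random_ratio_matrix(design, 2, seed=1)
        row = matrix.values.iloc[0]
        matrix.values.iloc[1] = 2 * row.mean() - row  # reflection about the mean
        cor = pairwise_correlation(_imputed(matrix))
        assert cor.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_against_two_pass_oracle(self, design):
        matrix = random_ratio_matrix(design, 10, seed=2)
        cor = pairwise_correlation(_imputed(matrix))
        values = matrix.values.to_numpy()
        for i in range(10):
            for j in range(10):
                xi, xj = values[i] - values[i].mean(), values[j] - values[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert abs(cor.values[i, j] - expected) < 1e-12

    def test_constant_row_removed_with_warning(self, design, caplog):
        matrix = random_ratio_matrix(design, 4, seed=3)
        matrix.values.iloc[2] = 1.0
        with caplog.at_level("WARNING"):
            cor = pairwise_correlation(_imputed(matrix))
        assert len(cor.protein_ids) == 3
        assert "p0002" not in cor.protein_ids
        assert "constant" in caplog.text

    def test_rejects_unimputed_matrix(self, design):
        matrix = random_ratio_matrix(design, 5, seed=0, missing_fraction=0.3)
        with pytest.raises(ValueError, match="imputed"):
            pairwise_correlation(matrix)


class TestSignedAdjacency:
    @pytest.mark.parametrize(
        "cor_value,expected",
        [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.5 ** 15)],
    )
    def test_power_formula(self, cor_value, expected):
        cor = CorrelationMatrix(
            values=np.array([[1.0, cor_value], [cor_value, 1.0]]),
            protein_ids=["a", "b"],
        )
        adj = signed_adjacency(cor, beta=15)
        assert adj.values[0, 1] == pytest.approx(expected, rel=1e-12)
        assert adj.values[0, 0] == 0.0

    def test_monotone_in_correlation(self):
        rng = np.random.default_rng(0)
        values = np.sort(rng.uniform(-1, 1, 50))
        cor = np.eye(51)
        cor[0, 1:] = values
        cor[1:, 0] = values
        adj = signed_adjacency(
            CorrelationMatrix(values=cor, protein_ids=[str(i) for i in range(51)]),
            beta=15,
        )
        assert (np.diff(adj.values[0, 1:]) >= 0).all()

    def test_beta_below_one_rejected(self):
        cor = CorrelationMatrix(values=np.eye(2), protein_ids=["a", "b"])
        with pytest.raises(ValueError):
            signed_adjacency(cor, beta=0)


class TestSoftThreshold:
    def test_power_law_connectivity_fits_well(self):
        # inverse-CDF sample from a truncated continuous power law
        gamma, k0, k1 = 2.5, 1.0, 100.0
        u = (np.arange(20000) + 0.5) / 20000
        a = 1 - gamma
        k = ((k1 ** a - k0 ** a) * u + k0 ** a) ** (1 / a)
        r2, slope = scale_free_fit(k, n_bins=10)
        assert r2 > 0.98
        assert slope < 0

    def test_fit_matches_independent_least_squares(self):
        rng = np.random.default_rng(4)
        k = rng.pareto(2.0, 500) + 0.5
        r2, slope = scale_free_fit(k, n_bins=10)
        # recompute binned regression independently
        edges = np.unique(np.quantile(k, np.linspace(0, 1, 11)))
        counts, _ = np.histogram(k, bins=edges)
        idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0,
                      len(edges) - 2)
        mean_k = np.array([k[idx == b].mean() for b in range(len(edges) - 1)])
        density = counts / (k.size * np.diff(edges))
        x, y = np.log10(mean_k), np.log10(density)
        design_matrix = np.vstack([x, np.ones_like(x)]).T
        beta_hat, *_ = np.linalg.lstsq(design_matrix, y, rcond=None)
        residual = y - design_matrix @ beta_hat
        ss_res = (residual ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        expected_r2 = 1 - ss_res / ss_tot
        assert slope == pytest.approx(beta_hat[0], abs=1e-10)
        assert abs(r2) == pytest.approx(expected_r2, abs=1e-10)

    def test_degenerate_equal_connectivities_undefined(self):
        r2, slope = scale_free_fit(np.full(100, 3.0))
        assert np.isnan(r2) and np.isnan(slope)

    def test_mean_connectivity_decreases_with_beta(self, design):
        matrix = _imputed(random_ratio_matrix(design, 30, seed=5))
        table = pick_soft_threshold(matrix, candidates=[2, 6, 10, 15, 20])
        assert (np.diff(table["mean_connectivity"]) < 0).all()

    def test_empty_candidates_rejected(self, design):
        matrix = _imputed(random_ratio_matrix(design, 10, seed=0))
        with pytest.raises(ValueError):
            pick_soft_threshold(matrix, candidates=[])


def tom_oracle(a):
    """O(n^3) triple-loop topological overlap."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def random_adjacency(n, rng):
    a = rng.uniform(0, 1, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


class TestTopologicalOverlap:
    def test_two_node_network(self):
        for a_value in (0.1, 0.5, 0.9):
            adj = AdjacencyMatrix(
                values=np.array([[0.0, a_value], [a_value, 0.0]]),
                protein_ids=["a", "b"],
            )
            tom = topological_overlap(adj)
            assert tom.values[0, 1] == pytest.approx(a_value, rel=1e-12)

    def test_complete_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = topological_overlap(
            AdjacencyMatrix(values=a, protein_ids=list("abc"))
        )
        np.testing.assert_allclose(tom.values, 1.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = random_adjacency(15, rng)
            tom = topological_overlap(
                AdjacencyMatrix(values=a, protein_ids=[str(i) for i in range(15)])
            )
            np.testing.assert_allclose(tom.values, tom_oracle(a), atol=1e-12)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(1)
        a = random_adjacency(30, rng)
        tom = topological_overlap(
            AdjacencyMatrix(values=a, protein_ids=[str(i) for i in range(30)])
        )
        assert (tom.values >= 0).all() and (tom.values <= 1).all()
        np.testing.assert_allclose(tom.values, tom.values.T)

    def test_isolated_pair_equals_adjacency(self):
        # block-diagonal: pair {0,1} disconnected from the rest
        a = np.zeros((6, 6))
        a[0, 1] = a[1, 0] = 0.7
        rest = random_adjacency(4, np.random.default_rng(2))
        a[2:, 2:] = rest
        tom = topological_overlap(
            AdjacencyMatrix(values=a, protein_ids=[str(i) for i in range(6)])
        )
        assert tom.values[0, 1] == pytest.approx(0.7, rel=1e-12)

    def test_rejects_nonzero_diagonal(self):
        a = np.ones((3, 3))
        with pytest.raises(ValueError, match="diagonal"):
            topological_overlap(AdjacencyMatrix(values=a, protein_ids=list("abc")))


def average_linkage_oracle(dissimilarity):
    """Naive O(n^3) average-linkage agglomeration; returns sorted merge heights."""
    clusters = {i: [i] for i in range(dissimilarity.shape[0])}
    heights = []
    while len(clusters) > 1:
        best = None
        for ci in sorted(clusters):
            for cj in sorted(clusters):
                if cj <= ci:
                    continue
                d = np.mean([
                    dissimilarity[u, v]
                    for u in clusters[ci] for v in clusters[cj]
                ])
                if best is None or d < best[0]:
                    best = (d, ci, cj)
        d, ci, cj = best
        heights.append(d)
        clusters[ci] = clusters[ci] + clusters.pop(cj)
    return np.array(heights)


class TestClusterDendrogram:
    def _block_tom(self, sizes, within=1.0, between=0.0):
        n = sum(sizes)
        values = np.full((n, n), between)
        start = 0
        for size in sizes:
            values[start:start + size, start:start + size] = within
            start += size
        np.fill_diagonal(values, 1.0)
        return TOMatrix(values=values, protein_ids=[f"p{i}" for i in range(n)])

    def test_two_perfect_blocks(self):
        tom = self._block_tom([4, 4])
        dendro = cluster_dendrogram(tom)
        heights = np.sort(dendro.heights())
        np.testing.assert_allclose(heights[:-1], 0.0, atol=1e-12)
        assert heights[-1] == pytest.approx(1.0)

    def test_single_protein(self):
        tom = TOMatrix(values=np.array([[1.0]]), protein_ids=["only"])
        dendro = cluster_dendrogram(tom)
        assert len(dendro.merges) == 0
        assert dendro.to_newick() == "only;"

    def test_matches_average_linkage_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 1, (12, 12))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 1.0)
        tom = TOMatrix(values=values, protein_ids=[f"p{i}" for i in range(12)])
        dendro = cluster_dendrogram(tom)
        expected = average_linkage_oracle(1.0 - values)
        np.testing.assert_allclose(
            np.sort(dendro.heights()), np.sort(expected), atol=1e-12
        )

    def test_heights_nondecreasing(self, design):
        matrix = _imputed(random_ratio_matrix(design, 40, seed=6))
        tom = topological_overlap(
            signed_adjacency(pairwise_correlation(matrix), beta=6)
        )
        dendro = cluster_dendrogram(tom)
        assert (np.diff(dendro.heights()) >= -1e-12).all()

    def test_newick_has_all_leaves(self):
        tom = self._block_tom([3, 2])
        newick = cluster_dendrogram(tom).to_newick()
        for pid in tom.protein_ids:
            assert pid in newick


class TestDynamicTreeCut:
    def _planted_tom(self, sizes, within=0.9, between=0.05, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        n = sum(sizes)
        values = np.full((n, n), between) + rng.uniform(0, noise, (n, n))
        start = 0
        for size in sizes:
            block = slice(start, start + size)
            values[block, block] = within + rng.uniform(0, noise, (size, size))
            start += size
        values = (values + values.T) / 2
        np.fill_diagonal(values, 1.0)
        return TOMatrix(values=np.clip(values, 0, 1),
                        protein_ids=[f"p{i:03d}" for i in range(n)])

    def test_three_planted_blocks_recovered(self):
        tom = self._planted_tom([20, 10, 5])
        assignment = dynamic_tree_cut(cluster_dendrogram(tom), tom)
        labels = assignment.labels
        assert set(labels) == {"turquoise", "blue", "brown"}
        blocks = [labels.iloc[:20], labels.iloc[20:30], labels.iloc[30:]]
        for block in blocks:
            assert block.nunique() == 1
        assert labels.iloc[0] == "turquoise"      # largest block first
        assert labels.iloc[20] == "blue"
        assert labels.iloc[30] == "brown"

    def test_block_below_minimum_size_goes_grey(self):
        tom = self._planted_tom([20, 4])
        assignment = dynamic_tree_cut(cluster_dendrogram(tom), tom,
                                      min_module_size=5)
        assert (assignment.labels.iloc[20:] == GREY).all()
        assert (assignment.labels.iloc[:20] == "turquoise").all()

    def test_uniform_tom_single_module(self):
        values = np.full((10, 10), 0.4)
        np.fill_diagonal(values, 1.0)
        tom = TOMatrix(values=values, protein_ids=[f"p{i}" for i in range(10)])
        assignment = dynamic_tree_cut(cluster_dendrogram(tom), tom)
        assert (assignment.labels == "turquoise").all()

    def test_uniform_tom_below_min_size_all_grey(self):
        values = np.full((4, 4), 0.4)
        np.fill_diagonal(values, 1.0)
        tom = TOMatrix(values=values, protein_ids=list("abcd"))
        assignment = dynamic_tree_cut(cluster_dendrogram(tom), tom,
                                      min_module_size=5)
        assert (assignment.labels == GREY).all()

    def test_permutation_invariance(self):
        tom = self._planted_tom([12, 8, 6], seed=4)
        assignment = dynamic_tree_cut(cluster_dendrogram(tom), tom)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(tom.protein_ids))
        shuffled = TOMatrix(
            values=tom.values[np.ix_(order, order)],
            protein_ids=[tom.protein_ids[i] for i in order],
        )
        assignment_shuffled = dynamic_tree_cut(
            cluster_dendrogram(shuffled), shuffled
        )
        pd.testing.assert_series_equal(
            assignment.labels.sort_index(), assignment_shuffled.labels.sort_index()
        )

    def test_invalid_min_module_size(self):
        tom = self._planted_tom([10])
        with pytest.raises(ValueError):
            dynamic_tree_cut(cluster_dendrogram(tom), tom, min_module_size=0)

    def test_static_cut_only(self):
        tom = self._planted_tom([10, 10], noise=0.0)
        assignment = dynamic_tree_cut(cluster_dendrogram(tom), tom,
                                      split_ratio=None)
        assert len(assignment.module_names()) == 2


class TestEndToEndRecovery:
    def test_recovery_on_default_synthetic_data(self, design, noisy_dataset):
        from sklearn.metrics import adjusted_rand_score

        from silacnet import filter_missingness

        matrix = impute_zero(filter_missingness(noisy_dataset.ratios, 14))
        cor = pairwise_correlation(matrix)
        tom = topological_overlap(signed_adjacency(cor, beta=15))
        assignment = dynamic_tree_cut(cluster_dendrogram(tom), tom)
        truth = noisy_dataset.truth_labels.loc[cor.protein_ids]
        non_grey = assignment.labels[assignment.labels != GREY]
        ari = adjusted_rand_score(truth.loc[non_grey.index], non_grey)
        assert ari >= 0.8


from hypothesis import given, settings
from hypothesis import strategies as st


class TestNetworkProperties:
    @given(seed=st.integers(min_value=0, max_value=10_000),
           n=st.integers(min_value=2, max_value=12))
    @settings(max_examples=40, deadline=None)
    def test_tom_bounded_and_dominates_isolated_edges(self, seed, n):
        rng = np.random.default_rng(seed)
        a = random_adjacency(n, rng)
        tom = topological_overlap(
            AdjacencyMatrix(values=a, protein_ids=[str(i) for i in range(n)])
        )
        assert (tom.values >= -1e-15).all() and (tom.values <= 1 + 1e-15).all()
        np.testing.assert_allclose(tom.values, tom_oracle(a), atol=1e-12)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_signed_adjacency_monotone(self, seed):
        rng = np.random.default_rng(seed)
        c1, c2 = np.sort(rng.uniform(-1, 1, 2))
        base = np.eye(3)
        base[0, 1] = base[1, 0] = c1
        base[0, 2] = base[2, 0] = c2
        adj = signed_adjacency(
            CorrelationMatrix(values=base, protein_ids=list("abc")), beta=15
        )
        assert adj.values[0, 1] <= adj.values[0, 2]
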