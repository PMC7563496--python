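"""Co-expression network construction: similarity, soft threshold, TOM, binarization."""

import numpy as np
import pytest

from scgenegroups.clustering import ClusterAssignment
from scgenegroups.de import select_de_genes
from scgenegroups.expression import ExpressionMatrix
from scgenegroups.network import (
    binarize_top_g,
    build_network,
    pearson_similarity,
    select_soft_threshold,
    soft_threshold,
    tom_from_adjacency,
    write_edge_list,
)
from scgenegroups.simulate import simulate_expression


def brute_force_tom(a):
    """Literal evaluation of the topological-overlap formula."""
    z = a.shape[0]
    t = np.eye(z)
    for i in range(z):
        for j in range(z):
            if i == j:
                continue
            shared = sum(a[i, m] * a[m, j] for m in range(z))
            ki = sum(a[i, m] for m in range(z))
            kj = sum(a[j, m] for m in range(z))
            t[i, j] = (shared + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return t


def random_adjacency(rng, z):
    a = rng.random((z, z))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


class TestPearsonSimilarity:
    def test_linear_dependence_gives_one(self, rng):
        base = rng.normal(size=20)
        values = np.vstack([base, 2 * base + 1, -base, rng.normal(size=20)])
        m = ExpressionMatrix(np.abs(values) + 1, list("abcd"),
                             [f"c{i}" for i in range(20)], "log")
        m.values[:] = values  # allow negatives on log scale
        w = pearson_similarity(m)
        assert w[0, 1] == pytest.approx(1.0)
        assert w[0, 2] == pytest.approx(1.0)  # absolute value of r = -1
        assert np.all(np.diag(w) == 0)

    def test_matches_brute_force_double_loop(self, rng):
        values = rng.normal(size=(5, 20))
        m = ExpressionMatrix(values - values.min(), [f"g{i}" for i in range(5)],
                             [f"c{j}" for j in range(20)], "log")
        w = pearson_similarity(m)
        for i in range(5):
            for j in range(i + 1, 5):
                x, y = m.values[i], m.values[j]
                r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                    np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
                )
                assert w[i, j] == pytest.approx(abs(r), abs=1e-12)

    def test_zero_variance_gene_raises_with_names(self):
        values = np.vstack([np.ones(10), np.arange(10, dtype=float)])
        m = ExpressionMatrix(values, ["flat", "ok"],
                             [f"c{j}" for j in range(10)], "log")
        with pytest.raises(ValueError, match="flat"):
            pearson_similarity(m)


class TestSoftThreshold:
    def test_single_candidate_returned(self, rng):
        assert select_soft_threshold(random_adjacency(rng, 20), [1]) == 1

    def test_scale_free_network_reaches_r2_target(self, rng):
        # similarity built from a preferential-attachment graph has a heavy
        # tailed connectivity distribution at beta = 1 already
        import networkx as nx

        graph = nx.barabasi_albert_graph(300, 2, seed=7)
        sim = nx.to_numpy_array(graph) * 0.9
        beta, table = select_soft_threshold(sim, range(1, 11), return_table=True)
        assert table.r_squared.max() >= 0.8

    def test_r_squared_matches_external_least_squares(self, rng):
        from scgenegroups.network import _scale_free_fit

        k = rng.pareto(2.0, size=400) + 1
        edges = np.geomspace(k.min(), k.max() + 1e-12, 11)
        counts, _ = np.histogram(k, bins=edges)
        centers = np.sqrt(edges[:-1] * edges[1:])
        ok = counts > 0
        x, y = np.log10(centers[ok]), np.log10(counts[ok])
        slope, intercept = np.polyfit(x, y, 1)
        ss_res = np.sum((y - slope * x - intercept) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        expected = 1 - ss_res / ss_tot if slope < 0 else 0.0
        assert _scale_free_fit(k, 10) == pytest.approx(expected, rel=1e-9)

    def test_degenerate_connectivity_warns_and_returns_smallest(self):
        sim = np.full((10, 10), 0.5)
        np.fill_diagonal(sim, 0.0)
        with pytest.warns(UserWarning, match="degenerate"):
            assert select_soft_threshold(sim, range(2, 8)) == 2

    def test_raising_beta_never_increases_adjacency(self, rng):
        w = random_adjacency(rng, 15)
        previous = soft_threshold(w, 1)
        for beta in range(2, 8):
            current = soft_threshold(w, beta)
            assert np.all(current <= previous + 1e-15)
            previous = current


class TestTOM:
    def test_all_zero_adjacency(self):
        t = tom_from_adjacency(np.zeros((4, 4)))
        assert np.all(t[~np.eye(4, dtype=bool)] == 0)
        assert np.all(np.diag(t) == 1)

    def test_isolated_unit_pair_has_overlap_one(self):
        a = np.zeros((5, 5))
        a[0, 1] = a[1, 0] = 1.0
        t = tom_from_adjacency(a)
        assert t[0, 1] == pytest.approx(1.0)

    def test_binary_clique_has_overlap_one(self):
        a = 1.0 - np.eye(5)
        t = tom_from_adjacency(a)
        # (n-2 shared neighbours + 1) / (n-1 + 1 - 1) = 1 for every pair
        assert np.allclose(t, 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(10):
            a = random_adjacency(rng, 10)
            np.testing.assert_allclose(
                tom_from_adjacency(a), brute_force_tom(a), atol=1e-12
            )

    def test_range_and_validation(self, rng):
        a = random_adjacency(rng, 12)
        t = tom_from_adjacency(a)
        assert t.min() >= 0 and t.max() <= 1
        with pytest.raises(ValueError, match="diagonal"):
            tom_from_adjacency(np.eye(3))
        with pytest.raises(ValueError, match="0, 1"):
            tom_from_adjacency(np.full((2, 2), 2.0) - 2 * np.eye(2))


class TestBinarize:
    def test_g100_gives_complete_graph(self, rng):
        t = random_adjacency(rng, 8)
        binary, edges, degrees = binarize_top_g(t, 100)
        assert edges == 8 * 7 // 2
        np.testing.assert_array_equal(degrees, np.full(8, 7))

    def test_bankers_rounding_of_edge_budget(self, rng):
        # 10 genes, g=10%: 0.10 * 45 = 4.5 -> 4 edges (round half to even)
        t = random_adjacency(rng, 10)
        _, edges, _ = binarize_top_g(t, 10)
        assert edges == 4

    def test_edges_are_exactly_the_top_values(self, rng):
        t = random_adjacency(rng, 12)
        binary, edges, _ = binarize_top_g(t, 20)
        iu = np.triu_indices(12, 1)
        cutoff = np.sort(t[iu])[::-1][edges - 1]
        chosen = t[iu][binary[iu] == 1]
        assert chosen.min() >= cutoff - 1e-15
        assert binary[iu].sum() == edges

    def test_ties_broken_deterministically(self):
        t = np.full((4, 4), 0.5)
        np.fill_diagonal(t, 0.0)
        binary, edges, _ = binarize_top_g(t, 50)
        # budget = round(0.5 * 6) = 3; lexicographically first pairs win
        assert edges == 3
        assert binary[0, 1] == binary[0, 2] == binary[0, 3] == 1
        assert binary[1, 2] == binary[1, 3] == binary[2, 3] == 0

    def test_empty_budget_is_an_error(self, rng):
        with pytest.raises(ValueError, match="empty network"):
            binarize_top_g(random_adjacency(rng, 5), 0.1)


@pytest.fixture(scope="module")
def built():
    m, truth = simulate_expression(
        n_cells=300, n_genes=600, n_clusters=3, de_per_cluster=100,
        effect_size=3.0, modules=[(10, 3.0)], seed=11,
    )
    assignment = ClusterAssignment(truth.cell_labels, 3, np.zeros((300, 3)))
    tables = select_de_genes(m, assignment)
    net = build_network(m, assignment, tables[1], g_percent=2.0, beta=6)
    return net, truth


class TestBuildNetwork:
    def test_module_pairs_dominate_top_edges(self, built):
        net, truth = built
        members = np.isin(net.gene_ids, truth.module_genes[0])
        internal = net.binary[np.ix_(members.nonzero()[0], members.nonzero()[0])]
        assert internal.sum() // 2 == 45  # all 45 module pairs are edges

    def test_edge_count_and_degrees_consistent(self, built):
        net, _ = built
        assert net.edge_count == net.binary.sum() // 2
        np.testing.assert_array_equal(net.degree_vector, net.binary.sum(axis=1))
        assert net.adjacency[net.similarity > 0].max() <= 1.0

    def test_eq2_adjacency_direct_evaluation(self, built):
        net, _ = built
        i, j = 0, 1
        assert net.adjacency[i, j] == pytest.approx(net.similarity[i, j] ** net.beta)
        assert soft_threshold(np.array([[0.0, 0.5], [0.5, 0.0]]), 2)[0, 1] == 0.25

    def test_two_disjoint_modules_give_separate_components(self):
        from scipy.sparse.csgraph import connected_components

        m, truth = simulate_expression(
            n_cells=200, n_genes=400, n_clusters=2, de_per_cluster=120,
            effect_size=3.0, modules=[(10, 3.0), (8, 3.0)], seed=4,
            module_within_cluster=False,
        )
        assignment = ClusterAssignment(truth.cell_labels, 2, np.zeros((200, 2)))
        tables = select_de_genes(m, assignment)
        net = build_network(m, assignment, tables[1], g_percent=1.5, beta=6)
        n_comp, comp = connected_components(net.binary, directed=False)
        for module in truth.module_genes:
            idx = np.isin(net.gene_ids, module).nonzero()[0]
            assert len(set(comp[idx])) == 1  # each module sits in one component
        labels_of = [comp[np.isin(net.gene_ids, mg).nonzero()[0][0]]
                     for mg in truth.module_genes]
        assert labels_of[0] != labels_of[1]

    def test_edge_list_round_trip(self, built, tmp_path):
        import json

        import pandas as pd

        net, _ = built
        write_edge_list(net, tmp_path / "edges.tsv")
        df = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        assert len(df) == net.edge_count
        meta = json.loads((tmp_path / "edges.tsv.json").read_text())
        assert meta["beta"] == net.beta and meta["n_edges"] == net.edge_count
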