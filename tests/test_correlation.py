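import math
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import floyd_warshall
from scipy.stats import chi2_contingency

from phytonet import correlation as corr
from phytonet.interactome import PlantProteinMatrix


class TestPhiCoefficient:
    def test_perfect_association(self):
        assert corr.phi_coefficient((5, 0, 0, 5)) == 1.0

    def test_closed_form_case(self):
        assert corr.phi_coefficient((4, 1, 1, 4)) == pytest.approx(0.6)

    def test_independence(self):
        assert corr.phi_coefficient((2, 2, 2, 2)) == 0.0

    def test_zero_marginal_returns_nan(self):
        assert math.isnan(corr.phi_coefficient((3, 2, 0, 0)))

    def test_all_zero_table_is_error(self):
        with pytest.raises(ValueError):
            corr.phi_coefficient((0, 0, 0, 0))

    def test_symmetry_and_sign_flip(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 30, 4)
            # swapping the two variables transposes the table (b <-> c)
            assert corr.phi_coefficient((a, b, c, d)) == pytest.approx(
                corr.phi_coefficient((a, c, b, d)))
            # complementing one variable swaps its rows: sign flips
            assert corr.phi_coefficient((c, d, a, b)) == pytest.approx(
                -corr.phi_coefficient((a, b, c, d)))

    def test_bounded_by_one(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            table = tuple(int(x) for x in rng.integers(0, 40, 4))
            if sum(table) == 0:
                continue
            phi = corr.phi_coefficient(table)
            if not math.isnan(phi):
                assert abs(phi) <= 1.0 + 1e-12


class TestPhiTest:
    def test_identity_chi2_equals_n_phi_squared(self):
        phi, chi2, _ = corr.phi_test((4, 1, 1, 4))
        assert chi2 == pytest.approx(10 * 0.36, abs=1e-12)

    def test_independence_gives_p_one(self):
        phi, chi2, p = corr.phi_test((2, 2, 2, 2))
        assert chi2 == 0.0 and p == 1.0

    def test_identity_and_oracle_on_random_tables(self):
        """chi2 = n*phi^2 to 1e-10 and equal to the uncorrected Pearson
        statistic on 1,000 random non-degenerate tables."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 1000:
            a, b, c, d = (int(x) for x in rng.integers(0, 25, 4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            phi, chi2, p = corr.phi_test((a, b, c, d))
            n = a + b + c + d
            assert abs(chi2 - n * phi * phi) < 1e-10
            oracle = chi2_contingency([[a, b], [c, d]], correction=False)
            assert chi2 == pytest.approx(oracle.statistic, abs=1e-10)
            assert p == pytest.approx(oracle.pvalue, abs=1e-10)
            checked += 1

    def test_degenerate_table_not_evaluable(self):
        phi, chi2, p = corr.phi_test((3, 2, 0, 0))
        assert all(math.isnan(v) for v in (phi, chi2, p))


def matrix_from(columns: dict[str, list[int]]) -> PlantProteinMatrix:
    inc = pd.DataFrame(columns)
    inc.index = [f"PL{i}" for i in range(len(inc))]
    return PlantProteinMatrix(incidence=inc, compound_counts=inc.copy())


class TestBuildPhiNetwork:
    def test_identical_columns_give_phi_one_edge(self):
        col = [1] * 10 + [0] * 10
        m = matrix_from({"A": col, "B": col, "C": [0] * 19 + [1]})
        net = corr.build_phi_network(m)
        edge = {frozenset((e.protein_a, e.protein_b)): e
                for e in net.edges}[frozenset({"A", "B"})]
        assert edge.phi == pytest.approx(1.0)
        assert edge.n == 20
        assert edge.p_adjusted <= 0.05

    def test_protein_targeted_by_all_plants_not_evaluable(self):
        m = matrix_from({"A": [1, 1, 1, 1], "B": [1, 0, 1, 0],
                         "C": [0, 1, 0, 1]})
        net = corr.build_phi_network(m)
        # A has a zero "not targeted" marginal: pairs with A are skipped
        assert net.n_tested == 1
        assert all("A" not in (e.protein_a, e.protein_b)
                   for e in net.edges)

    def test_bonferroni_shrinks_with_alpha(self):
        rng = np.random.default_rng(12)
        cols = {f"T{i}": rng.integers(0, 2, 30).tolist()
                for i in range(12)}
        m = matrix_from(cols)
        loose = corr.build_phi_network(m, alpha=0.5)
        tight = corr.build_phi_network(m, alpha=0.01)
        loose_set = {frozenset((e.protein_a, e.protein_b))
                     for e in loose.edges}
        tight_set = {frozenset((e.protein_a, e.protein_b))
                     for e in tight.edges}
        assert tight_set <= loose_set

    def test_node_sizes_are_plant_counts(self):
        m = matrix_from({"A": [1, 1, 0], "B": [1, 0, 0]})
        net = corr.build_phi_network(m)
        assert net.node_sizes == {"A": 2, "B": 1}

    def test_negative_significant_edges_retained(self):
        col = [1] * 10 + [0] * 10
        anti = [0] * 10 + [1] * 10
        m = matrix_from({"A": col, "B": anti, "C": [1] * 19 + [0]})
        net = corr.build_phi_network(m)
        phis = {frozenset((e.protein_a, e.protein_b)): e.phi
                for e in net.edges}
        assert phis[frozenset({"A", "B"})] == pytest.approx(-1.0)

    def test_fewer_than_two_targeted_proteins_is_error(self):
        m = matrix_from({"A": [1, 0], "B": [0, 0]})
        with pytest.raises(ValueError):
            corr.build_phi_network(m)


class TestPlantedRecovery:
    def test_phi_network_recovers_planted_clusters(self, pipeline_result):
        """>= 90% of intra-cluster pairs significant, <= 5% spurious
        inter-cluster edges, on the default generator at fixed seed."""
        truth = pipeline_result.dataset.truth
        edges = {frozenset((e.protein_a, e.protein_b))
                 for e in pipeline_result.phi_network.edges}
        intra = set()
        for cluster in truth.planted_clusters:
            intra |= {frozenset(p)
                      for p in combinations(sorted(cluster), 2)}
        inter = set()
        for c1, c2 in combinations(truth.planted_clusters, 2):
            inter |= {frozenset((a, b)) for a in c1 for b in c2}
        assert len(edges & intra) / len(intra) >= 0.9
        assert len(edges & inter) / len(inter) <= 0.05

    def test_single_planted_cluster_fully_recovered(self):
        """A 3-protein cluster targeted by 10 of 20 plants yields all 3
        intra-cluster edges as significant."""
        from phytonet import pipeline as pl
        from phytonet.synthetic_data import GeneratorConfig

        cfg = pl.PipelineConfig(
            generator=GeneratorConfig(n_plants=20,
                                      planted_clusters=((10, 3),),
                                      rng_seed=5))
        result = pl.run(cfg)
        cluster = result.dataset.truth.planted_clusters[0]
        edges = {frozenset((e.protein_a, e.protein_b))
                 for e in result.phi_network.edges}
        wanted = {frozenset(p) for p in combinations(sorted(cluster), 2)}
        assert wanted <= edges


class TestComponentsAndBridges:
    def net_from_edges(self, edge_list):
        g = nx.Graph()
        g.add_edges_from(edge_list)
        return g

    def test_two_triangles_sharing_a_node(self):
        g = self.net_from_edges([("a", "b"), ("b", "c"), ("a", "c"),
                                 ("c", "d"), ("d", "e"), ("c", "e")])
        components, bridges = corr.components_and_bridges(g)
        assert len(components) == 1
        assert bridges == {"c"}

    def test_single_edge(self):
        components, bridges = corr.components_and_bridges(
            self.net_from_edges([("a", "b")]))
        assert components == [{"a", "b"}]
        assert bridges == set()

    def test_matches_node_deletion_oracle(self):
        g = nx.gnp_random_graph(50, 0.08, seed=42)
        _, bridges = corr.components_and_bridges(g)
        connected = g.subgraph([n for n in g if g.degree(n) > 0])
        base = nx.number_connected_components(connected)
        expected = set()
        for node in connected.nodes:
            h = nx.Graph(connected)
            h.remove_node(node)
            if nx.number_connected_components(h) > base:
                expected.add(node)
        assert bridges == expected


class TestIntraClusterDistance:
    def test_path_graph(self):
        mean, mx, unreachable = corr.intra_cluster_distance(
            {"A", "C"}, [("A", "B"), ("B", "C")])
        assert mean == 2.0 and mx == 2.0 and unreachable == 0

    def test_triangle(self):
        mean, mx, unreachable = corr.intra_cluster_distance(
            {"A", "B", "C"}, [("A", "B"), ("B", "C"), ("A", "C")])
        assert mean == 1.0 and mx == 1.0 and unreachable == 0

    def test_unreachable_pairs_counted(self):
        mean, mx, unreachable = corr.intra_cluster_distance(
            {"A", "B", "Z"}, [("A", "B")])
        assert mean == 1.0 and unreachable == 2

    def test_too_small_set_is_error(self):
        with pytest.raises(ValueError):
            corr.intra_cluster_distance({"A"}, [("A", "B")])

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(6)
        g = nx.gnp_random_graph(40, 0.1, seed=11)
        members = sorted(rng.choice(40, size=15, replace=False).tolist())
        mean, mx, unreachable = corr.intra_cluster_distance(
            members, list(g.edges))
        adj = nx.to_numpy_array(g, nodelist=range(40))
        dist = floyd_warshall(adj, unweighted=True)
        vals = [dist[i, j] for i, j in combinations(members, 2)]
        finite = [v for v in vals if np.isfinite(v)]
        assert mean == pytest.approx(np.mean(finite))
        assert mx == max(finite)
        assert unreachable == sum(1 for v in vals if not np.isfinite(v))
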