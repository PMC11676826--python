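import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phenet import topology_metrics as tm


def categorised_graph(edges, categories):
    g = nx.Graph()
    g.add_edges_from(edges)
    for node, cat in categories.items():
        g.nodes[node]["category"] = cat
    return g


class TestHScore:
    def test_printed_value_085(self):
        # degree 13, neighbour split 12/1, 17 categories
        _, scaled = tm.h_score([12, 1], 17)
        assert round(scaled, 2) == 0.85

    def test_printed_value_013(self):
        # degree 11, split 4,2,1,1,1,1,1, 17 categories
        _, scaled = tm.h_score([4, 2, 1, 1, 1, 1, 1], 17)
        assert round(scaled, 2) == 0.13

    def test_single_category_neighbourhood_is_unity(self):
        for k in (1, 2, 5, 40):
            _, scaled = tm.h_score([k], 17)
            assert scaled == pytest.approx(1.0)

    def test_degree_one_is_unity(self):
        raw, scaled = tm.h_score([1], 17)
        assert raw == pytest.approx(1.0) and scaled == 1.0

    def test_most_even_split_is_zero(self):
        _, scaled = tm.h_score([1, 1, 1], 17)
        assert scaled == pytest.approx(0.0)

    def test_zeros_in_counts_ignored(self):
        assert tm.h_score([12, 0, 1, 0], 17) == tm.h_score([12, 1], 17)

    def test_raw_is_sum_of_squared_shares(self):
        raw, _ = tm.h_score([3, 1], 17)
        assert raw == pytest.approx((3 / 4) ** 2 + (1 / 4) ** 2)

    def test_scaled_in_unit_interval(self, rng):
        for _ in range(200):
            c = int(rng.integers(2, 18))
            parts = rng.integers(1, 8, size=int(rng.integers(1, c + 1)))
            _, scaled = tm.h_score(parts.tolist(), c)
            assert -1e-12 <= scaled <= 1 + 1e-12

    def test_no_neighbours_rejected(self):
        with pytest.raises(ValueError, match="neighbour"):
            tm.h_score([], 17)

    def test_single_category_universe_rejected(self):
        with pytest.raises(ValueError, match="two possible categories"):
            tm.h_score([3], 1)


class TestHStarMin:
    @pytest.mark.parametrize("k, c, expected", [
        (1, 17, 1.0),
        (5, 17, 1 / 5),
        (17, 17, 1 / 17),
        (5, 2, (3 ** 2 + 2 ** 2) / 25),  # most even split 3/2
        (20, 3, (2 * 7 ** 2 + 6 ** 2) / 400),  # split 7,7,6
    ])
    def test_values(self, k, c, expected):
        assert tm._h_star_min(k, c) == pytest.approx(expected)

    def test_is_true_minimum_by_enumeration(self):
        """Oracle: enumerate all compositions of k over c categories."""
        for k, c in [(4, 2), (5, 3), (6, 4)]:
            best = min(
                sum((x / k) ** 2 for x in parts)
                for parts in itertools.product(range(k + 1), repeat=c)
                if sum(parts) == k)
            assert tm._h_star_min(k, c) == pytest.approx(best)


class TestModularity:
    def _random_weighted(self, rng, n):
        g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(1 << 30)))
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.uniform(0.1, 2.0))
        return g

    def test_matches_direct_double_sum(self, rng):
        """Oracle: the literal Eq double sum over all node pairs."""
        for _ in range(10):
            n = int(rng.integers(4, 21))
            g = self._random_weighted(rng, n)
            if g.number_of_edges() == 0:
                continue
            labels = {v: int(rng.integers(3)) for v in g.nodes}
            nodes = list(g.nodes)
            a = nx.to_numpy_array(g, nodelist=nodes)
            m2 = a.sum()
            k = a.sum(axis=1)
            q = 0.0
            for i in range(n):
                for j in range(n):
                    if labels[nodes[i]] == labels[nodes[j]]:
                        q += (a[i, j] - k[i] * k[j] / m2) / m2
            assert tm.modularity(g, labels) == pytest.approx(q, abs=1e-12)

    def test_matches_networkx(self, rng):
        g = self._random_weighted(rng, 15)
        labels = {v: v % 3 for v in g.nodes}
        communities = [{v for v in g.nodes if labels[v] == m} for m in range(3)]
        expected = nx.community.modularity(g, communities, weight="weight")
        assert tm.modularity(g, labels) == pytest.approx(expected, abs=1e-12)

    def test_two_cliques_partition(self):
        g = nx.Graph()
        for i, j in itertools.combinations(range(4), 2):
            g.add_edge(f"a{i}", f"a{j}", weight=1.0)
            g.add_edge(f"b{i}", f"b{j}", weight=1.0)
        g.add_edge("a0", "b0", weight=1.0)
        labels = {v: v[0] for v in g.nodes}
        # Q = sum_c (in_c/m - (k_c/2m)^2) for the two modules
        m = 13.0
        expected = 2 * (6 / m - (13 / (2 * m)) ** 2)
        assert tm.modularity(g, labels) == pytest.approx(expected)

    def test_single_module_is_zero(self):
        g = nx.path_graph(5)
        assert tm.modularity(g, {v: 0 for v in g.nodes}) == pytest.approx(0.0)

    def test_negative_weight_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=-1.0)
        with pytest.raises(ValueError, match="nonnegative"):
            tm.modularity(g, {"a": 0, "b": 0})

    def test_empty_graph_rejected(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ValueError, match="no links"):
            tm.modularity(g, {"a": 0, "b": 1})


class TestLouvain:
    def _two_cliques(self):
        g = nx.Graph()
        for i, j in itertools.combinations(range(5), 2):
            g.add_edge(f"a{i}", f"a{j}", weight=1.0)
            g.add_edge(f"b{i}", f"b{j}", weight=1.0)
        g.add_edge("a0", "b0", weight=0.5)
        return g

    def test_recovers_planted_modules(self):
        part = tm.louvain_partition(self._two_cliques(), seed=0)
        modules = {}
        for node, m in part.membership.items():
            modules.setdefault(m, set()).add(node)
        assert {frozenset(m) for m in modules.values()} == {
            frozenset(f"a{i}" for i in range(5)),
            frozenset(f"b{i}" for i in range(5))}

    def test_q_is_internally_consistent(self):
        g = self._two_cliques()
        part = tm.louvain_partition(g, seed=3)
        assert part.q == pytest.approx(tm.modularity(g, part.membership))

    def test_deterministic_given_seed(self):
        g = self._two_cliques()
        a = tm.louvain_partition(g, seed=5)
        b = tm.louvain_partition(g, seed=5)
        assert a.membership == b.membership and a.q == b.q


class TestNodeHScores:
    def _graph(self):
        # hub with 3 neighbours: 2 in cat X, 1 in cat Y
        return categorised_graph(
            [("hub", "n1"), ("hub", "n2"), ("hub", "n3")],
            {"hub": "Y", "n1": "X", "n2": "X", "n3": "Y"})

    def test_values(self):
        table = tm.node_h_scores(self._graph()).set_index("node")
        raw, scaled = tm.h_score([2, 1], 2)
        assert table.at["hub", "h_raw"] == pytest.approx(raw)
        assert table.at["hub", "h_scaled"] == pytest.approx(scaled)
        assert table.at["n1", "h_scaled"] == 1.0  # degree-1
        assert table.at["hub", "degree"] == 3

    def test_n_categories_override(self):
        table = tm.node_h_scores(self._graph(), n_categories=17)
        hub = table.set_index("node").at["hub", "h_scaled"]
        assert hub == pytest.approx(tm.h_score([2, 1], 17)[1])


class TestMeanHTests:
    def _assortative(self):
        """Two category-pure cliques joined by one link: strongly
        homogeneous neighbourhoods."""
        edges, cats = [], {}
        for grp, cat in (("a", "X"), ("b", "Y")):
            for i, j in itertools.combinations(range(5), 2):
                edges.append((f"{grp}{i}", f"{grp}{j}"))
            for i in range(5):
                cats[f"{grp}{i}"] = cat
        edges.append(("a0", "b0"))
        return categorised_graph(edges, cats)

    def test_assortative_graph_rejects_null(self):
        res = tm.mean_h_tests(self._assortative(), grouping="all",
                              n_reps=200, seed=1)
        assert len(res) == 1
        row = res.iloc[0]
        assert row["mean_h"] > 0.8 and row["p_adj"] < 0.05

    def test_category_grouping_rows(self):
        res = tm.mean_h_tests(self._assortative(), grouping="category",
                              n_reps=50, seed=1)
        assert sorted(res["group"]) == ["X", "Y"]
        assert (res["p_adj"] >= res["p_raw"]).all()
        assert (res["p_adj"] <= 1.0).all()

    def test_module_grouping_requires_partition(self):
        with pytest.raises(ValueError, match="partition"):
            tm.mean_h_tests(self._assortative(), grouping="module")

    def test_module_grouping(self):
        g = self._assortative()
        part = tm.louvain_partition(g, seed=0)
        res = tm.mean_h_tests(g, grouping="module",
                              partition=part.membership, n_reps=50, seed=1)
        assert len(res) == len(set(part.membership.values()))

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError, match="grouping"):
            tm.mean_h_tests(self._assortative(), grouping="degree")

    def test_deterministic_given_seed(self):
        g = self._assortative()
        a = tm.mean_h_tests(g, grouping="all", n_reps=50, seed=4)
        b = tm.mean_h_tests(g, grouping="all", n_reps=50, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestCategoryZScores:
    def test_within_category_enrichment_sign(self):
        """All links inside one category in a 2-category network: positive
        z on the (X, X) diagonal, negative on (X, Y)."""
        g = nx.Graph()
        for i, j in itertools.combinations(range(5), 2):
            g.add_edge(f"x{i}", f"x{j}")
        g.add_nodes_from(f"y{i}" for i in range(5))
        for node in g.nodes:
            g.nodes[node]["category"] = "X" if node.startswith("x") else "Y"
        res = tm.category_z_scores(g, n_reps=300, seed=2).set_index(
            ["cat_i", "cat_j"])
        assert res.at[("X", "X"), "z"] > 0
        assert res.at[("X", "Y"), "z"] < 0

    def test_row_count_and_threshold(self):
        g = categorised_graph([("a", "b"), ("b", "c")],
                              {"a": "X", "b": "Y", "c": "Z"})
        res = tm.category_z_scores(g, n_reps=50, seed=0)
        assert len(res) == 3 * 4 // 2  # c(c+1)/2 unordered pairs incl. diagonal

    def test_sigma_zero_unscored(self):
        # two nodes, one link: every relabelling gives the same count
        g = categorised_graph([("a", "b")], {"a": "X", "b": "Y"})
        res = tm.category_z_scores(g, n_reps=20, seed=0)
        xy = res[(res["cat_i"] == "X") & (res["cat_j"] == "Y")].iloc[0]
        assert not xy["scored"] and not xy["significant"]
        assert np.isnan(xy["z"])

    def test_single_category_rejected(self):
        g = categorised_graph([("a", "b")], {"a": "X", "b": "X"})
        with pytest.raises(ValueError, match="two categories"):
            tm.category_z_scores(g)

    def test_matches_exact_enumeration_small(self):
        """Oracle on 4 nodes: null mean/sd over ALL label permutations."""
        import math
        g = categorised_graph([("a", "b"), ("c", "d")],
                              {"a": "X", "b": "X", "c": "Y", "d": "Y"})
        nodes = sorted(g.nodes)
        cats = [g.nodes[n]["category"] for n in nodes]
        xx_counts = []
        for perm in itertools.permutations(range(4)):
            relabel = {nodes[i]: cats[perm[i]] for i in range(4)}
            xx = sum(relabel[u] == relabel[v] == "X" for u, v in g.edges)
            xx_counts.append(xx)
        mu = np.mean(xx_counts)
        sd = np.std(xx_counts)
        res = tm.category_z_scores(g, n_reps=5000, seed=0).set_index(
            ["cat_i", "cat_j"])
        assert res.at[("X", "X"), "mu"] == pytest.approx(mu, abs=0.03)
        assert res.at[("X", "X"), "sigma"] == pytest.approx(sd, abs=0.03)


class TestPartitionTable:
    def test_contents(self):
        g = categorised_graph([("101", "102")],
                              {"101": "X", "102": "Y"})
        h = tm.node_h_scores(g)
        part = {"101": 0, "102": 0}
        table = tm.partition_table(g, part, h)
        assert list(table.columns) == ["phenocode", "category", "module",
                                       "h_scaled"]
        assert list(table["phenocode"]) == ["101", "102"]
        assert (table["h_scaled"] == 1.0).all()
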