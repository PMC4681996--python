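"""Map-equation clustering: objective values, optimizer, planted partitions."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

import trialscape as ts
from trialscape.clustering import one_module_partition, singleton_partition


def entropy_map_equation(graph, assignment):
    """Independent term-by-term oracle: L = q H(Q) + sum_m p_m H(P_m)."""
    strength = dict(graph.degree(weight="weight"))
    total = sum(strength.values())
    p = {v: s / total for v, s in strength.items()}
    modules = sorted(set(assignment.values()))
    q = {}
    for m in modules:
        q[m] = sum(
            w
            for u, v, w in graph.edges(data="weight", default=1.0)
            if (assignment[u] == m) != (assignment[v] == m)
        ) / total
    q_tot = sum(q.values())

    def H(probs):
        probs = [x for x in probs if x > 0]
        return -sum(x * math.log2(x) for x in probs)

    L = q_tot * H([q[m] / q_tot for m in modules]) if q_tot > 0 else 0.0
    for m in modules:
        members = [v for v in assignment if assignment[v] == m]
        p_circ = q[m] + sum(p[v] for v in members)
        if p_circ > 0:
            L += p_circ * H([q[m] / p_circ] + [p[v] / p_circ for v in members])
    return L


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def two_cliques():
    g = nx.Graph()
    for group in ("ABC", "DEF"):
        for u, v in itertools.combinations(group, 2):
            g.add_edge(u, v, weight=1.0)
    return g


class TestVisitRates:
    def test_two_nodes_split_evenly(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=7.0)
        flow = ts.visit_rates(g)
        assert flow.visit_rates == {"a": 0.5, "b": 0.5}

    def test_star_center_carries_half_the_flow(self):
        g = nx.Graph()
        for leaf in "xyz":
            g.add_edge("c", leaf, weight=1.0)
        flow = ts.visit_rates(g)
        assert flow.visit_rates["c"] == pytest.approx(0.5)
        for leaf in "xyz":
            assert flow.visit_rates[leaf] == pytest.approx(1 / 6)

    def test_rates_sum_to_one_on_random_graphs(self, rng):
        g = nx.gnm_random_graph(12, 25, seed=4)
        nx.set_edge_attributes(g, {e: float(rng.integers(1, 9)) for e in g.edges}, "weight")
        g.remove_nodes_from(list(nx.isolates(g)))
        assert sum(ts.visit_rates(g).visit_rates.values()) == pytest.approx(1.0)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            ts.visit_rates(nx.Graph())


class TestMapEquation:
    def test_one_module_equals_visit_rate_entropy(self):
        g = two_cliques()
        flow = ts.visit_rates(g)
        expected = -sum(p * math.log2(p) for p in flow.visit_rates.values())
        assert ts.map_equation(g, one_module_partition(g)) == pytest.approx(expected)

    def test_two_cliques_prefer_two_modules(self):
        g = two_cliques()
        two = {v: (0 if v in "ABC" else 1) for v in g}
        assert ts.map_equation(g, two) < ts.map_equation(g, one_module_partition(g))

    def test_agrees_with_entropy_oracle_on_random_partitions(self, rng):
        g = nx.gnm_random_graph(9, 18, seed=7)
        nx.set_edge_attributes(g, {e: float(rng.integers(1, 6)) for e in g.edges}, "weight")
        g.remove_nodes_from(list(nx.isolates(g)))
        nodes = list(g.nodes)
        for _ in range(12):
            assignment = {v: int(rng.integers(0, 3)) for v in nodes}
            assert ts.map_equation(g, assignment) == pytest.approx(
                entropy_map_equation(g, assignment)
            )

    def test_invariant_under_node_relabeling(self, rng):
        g = nx.gnm_random_graph(8, 14, seed=3)
        nx.set_edge_attributes(g, {e: float(rng.integers(1, 6)) for e in g.edges}, "weight")
        g.remove_nodes_from(list(nx.isolates(g)))
        nodes = list(g.nodes)
        perm = dict(zip(nodes, rng.permutation(nodes)))
        h = nx.relabel_nodes(g, perm)
        assignment = {v: int(rng.integers(0, 3)) for v in nodes}
        mapped = {perm[v]: m for v, m in assignment.items()}
        assert ts.map_equation(g, assignment) == pytest.approx(ts.map_equation(h, mapped))


class TestDetectClusters:
    def test_disconnected_cliques_become_components(self):
        part = ts.detect_clusters(two_cliques(), seed=0)
        assert part.n_clusters == 2
        assert part.clusters() == [["A", "B", "C"], ["D", "E", "F"]]

    def test_matches_brute_force_on_five_nodes(self):
        g = nx.Graph()
        for u, v, w in [("a", "b", 5), ("a", "c", 4), ("b", "c", 6), ("c", "d", 1), ("d", "e", 7)]:
            g.add_edge(u, v, weight=float(w))
        partitions = list(set_partitions(list(g.nodes)))
        assert len(partitions) == 52  # Bell(5)
        best = min(
            ts.map_equation(g, {n: i for i, blk in enumerate(pp) for n in blk})
            for pp in partitions
        )
        found = ts.detect_clusters(g, seed=1, n_restarts=8)
        assert found.codelength == pytest.approx(best)

    def test_never_worse_than_baseline_partitions(self, rng):
        g = nx.gnm_random_graph(10, 20, seed=9)
        nx.set_edge_attributes(g, {e: float(rng.integers(1, 5)) for e in g.edges}, "weight")
        g.remove_nodes_from(list(nx.isolates(g)))
        part = ts.detect_clusters(g, seed=2)
        assert part.codelength <= ts.map_equation(g, singleton_partition(g)) + 1e-9
        assert part.codelength <= ts.map_equation(g, one_module_partition(g)) + 1e-9

    def test_no_single_node_move_improves(self, rng):
        g = nx.gnm_random_graph(12, 30, seed=5)
        nx.set_edge_attributes(g, {e: float(rng.integers(1, 5)) for e in g.edges}, "weight")
        g.remove_nodes_from(list(nx.isolates(g)))
        part = ts.detect_clusters(g, seed=3)
        base = part.codelength
        modules = set(part.assignment.values())
        for v in g.nodes:
            for m in modules:
                trial = dict(part.assignment)
                trial[v] = m
                assert ts.map_equation(g, trial) >= base - 1e-9

    def test_recovers_planted_partition(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(6)
        sizes = [8, 8, 8]
        labels = sum(([i] * s for i, s in enumerate(sizes)), [])
        g = nx.Graph()
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                if labels[i] == labels[j]:
                    g.add_edge(i, j, weight=float(rng.integers(8, 12)))
                elif rng.random() < 0.15:
                    g.add_edge(i, j, weight=1.0)
        part = ts.detect_clusters(g, seed=4, n_restarts=8)
        found = [part.assignment[i] for i in range(len(labels))]
        assert adjusted_rand_score(labels, found) == 1.0

    def test_deterministic_given_seed(self):
        g = two_cliques()
        g.add_edge("C", "D", weight=0.5)
        a = ts.detect_clusters(g, seed=11)
        b = ts.detect_clusters(g, seed=11)
        assert a.assignment == b.assignment and a.codelength == b.codelength

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            ts.detect_clusters(nx.Graph())
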