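"""Flow-based clustering of co-occurrence networks via the two-level map equation.

A random walker on an undirected weighted network visits node i with
stationary probability p_i proportional to its strength.  A two-level
description of the walk assigns every node to a module; the expected
description length per step is

    L(M) = q H(Q) + sum_m p_m^circ H(P_m)

where q is the total module-exit rate, H(Q) the entropy of exit rates across
modules and H(P_m) the entropy of within-module visit (and exit) rates.
Using h(x) = x log2 x this expands to

    L = h(q) - 2 sum_m h(q_m) + sum_m h(q_m + p_m) - sum_i h(p_i),

which the optimizer evaluates incrementally.  Minimizing L concentrates flow
within modules: countries that persistently collaborate end up in one cluster.

The search is a greedy agglomeration (merge the connected module pair that
most decreases L) followed by single-node refinement sweeps, restarted from
shuffled node orders; connected components are clustered independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx
import numpy as np


def _h(x: float) -> float:
    return x * math.log2(x) if x > 0 else 0.0


@dataclass(frozen=True)
class FlowNetwork:
    """Stationary visit rates of an undirected weighted network."""

    nodes: tuple[Hashable, ...]
    visit_rates: Mapping[Hashable, float]  # p_i, summing to 1


@dataclass(frozen=True)
class Partition:
    """A hard partition of nodes with its map-equation value in bits."""

    assignment: Mapping[Hashable, int]  # node -> contiguous cluster id
    codelength: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> list[list[Hashable]]:
        out: dict[int, list] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return [sorted(out[cid], key=str) for cid in sorted(out)]


def visit_rates(graph: nx.Graph) -> FlowNetwork:
    """Strength-proportional stationary visit rates (undirected flow)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    strength = dict(graph.degree(weight="weight"))
    total = sum(strength.values())
    if total <= 0:
        raise ValueError("network has no positive-weight edges")
    return FlowNetwork(
        nodes=tuple(graph.nodes),
        visit_rates={n: s / total for n, s in strength.items()},
    )


def map_equation(graph: nx.Graph, assignment: Mapping[Hashable, int]) -> float:
    """Two-level map-equation value L (bits) of a partition of ``graph``.

    Nodes with zero strength carry no flow and do not contribute.
    """
    strength = dict(graph.degree(weight="weight"))
    total = sum(strength.values())  # = 2W
    if total <= 0:
        raise ValueError("network has no positive-weight edges")
    p = {n: s / total for n, s in strength.items()}
    p_mod: dict[int, float] = {}
    for n, m in assignment.items():
        p_mod[m] = p_mod.get(m, 0.0) + p.get(n, 0.0)
    q_mod: dict[int, float] = {m: 0.0 for m in p_mod}
    for u, v, w in graph.edges(data="weight", default=1.0):
        mu, mv = assignment[u], assignment[v]
        if mu != mv:
            q_mod[mu] += w / total
            q_mod[mv] += w / total
    q = sum(q_mod.values())
    L = _h(q) - sum(p_i and _h(p_i) for p_i in p.values())
    for m in p_mod:
        L += -2.0 * _h(q_mod[m]) + _h(q_mod[m] + p_mod[m])
    return L


class _Mutable:
    """Working state of the optimizer on one connected component."""

    def __init__(self, graph: nx.Graph, nodes: list):
        self.nodes = nodes
        self.index = {n: i for i, n in enumerate(nodes)}
        n = len(nodes)
        strength = dict(graph.degree(weight="weight"))
        total_all = sum(strength[v] for v in nodes)
        self.p = np.array([strength[v] / total_all for v in nodes])
        # normalized adjacency (w / 2W restricted to the component)
        self.adj: list[dict[int, float]] = [dict() for _ in range(n)]
        for u, v, w in graph.edges(nodes, data="weight", default=1.0):
            if u == v:
                continue
            iu, iv = self.index[u], self.index[v]
            self.adj[iu][iv] = self.adj[iu].get(iv, 0.0) + w / total_all
            self.adj[iv][iu] = self.adj[iv].get(iu, 0.0) + w / total_all
        self.module = np.arange(n)
        self.p_mod = self.p.copy()
        self.q_mod = np.array([sum(self.adj[i].values()) for i in range(n)])
        self.q = float(self.q_mod.sum())

    def node_to_module_weights(self, i: int) -> dict[int, float]:
        out: dict[int, float] = {}
        for j, w in self.adj[i].items():
            m = int(self.module[j])
            out[m] = out.get(m, 0.0) + w
        return out

    def codelength(self) -> float:
        L = _h(self.q)
        for m in np.unique(self.module):
            L += -2.0 * _h(self.q_mod[m]) + _h(self.q_mod[m] + self.p_mod[m])
        for pi in self.p:
            L -= _h(pi)
        return L

    def delta_move(self, i: int, target: int, links: dict[int, float]) -> float:
        """Change in L when node i moves from its module to ``target``."""
        src = int(self.module[i])
        if src == target:
            return 0.0
        pi = self.p[i]
        w_src = links.get(src, 0.0)  # weight from i into the rest of src
        w_tgt = links.get(target, 0.0)
        q_src_new = self.q_mod[src] - pi + 2.0 * w_src
        q_tgt_new = self.q_mod[target] + pi - 2.0 * w_tgt
        q_new = self.q + (q_src_new - self.q_mod[src]) + (q_tgt_new - self.q_mod[target])
        dL = _h(q_new) - _h(self.q)
        dL += -2.0 * (_h(q_src_new) - _h(self.q_mod[src]))
        dL += -2.0 * (_h(q_tgt_new) - _h(self.q_mod[target]))
        dL += _h(q_src_new + self.p_mod[src] - pi) - _h(self.q_mod[src] + self.p_mod[src])
        dL += _h(q_tgt_new + self.p_mod[target] + pi) - _h(self.q_mod[target] + self.p_mod[target])
        return dL

    def apply_move(self, i: int, target: int, links: dict[int, float]) -> None:
        src = int(self.module[i])
        pi = self.p[i]
        w_src = links.get(src, 0.0)
        w_tgt = links.get(target, 0.0)
        q_src_new = self.q_mod[src] - pi + 2.0 * w_src
        q_tgt_new = self.q_mod[target] + pi - 2.0 * w_tgt
        self.q += (q_src_new - self.q_mod[src]) + (q_tgt_new - self.q_mod[target])
        self.q_mod[src] = q_src_new
        self.q_mod[target] = q_tgt_new
        self.p_mod[src] -= pi
        self.p_mod[target] += pi
        self.module[i] = target


def _optimize_component(graph: nx.Graph, nodes: list, rng: np.random.Generator) -> dict:
    state = _Mutable(graph, nodes)
    n = len(nodes)

    # greedy agglomeration: repeatedly take the connected module pair whose
    # merge most decreases L; ties by smallest sorted module-id pair
    improved = True
    while improved:
        improved = False
        # inter-module link weights
        between: dict[tuple[int, int], float] = {}
        for i in range(n):
            mi = int(state.module[i])
            for j, w in state.adj[i].items():
                mj = int(state.module[j])
                if mi < mj:
                    between[(mi, mj)] = between.get((mi, mj), 0.0) + w
        best = (0.0, None)
        for (a, b) in sorted(between):
            w_ab = between[(a, b)]
            q_ab = state.q_mod[a] + state.q_mod[b] - 2.0 * w_ab
            q_new = state.q - 2.0 * w_ab
            dL = _h(q_new) - _h(state.q)
            dL += -2.0 * (_h(q_ab) - _h(state.q_mod[a]) - _h(state.q_mod[b]))
            dL += (
                _h(q_ab + state.p_mod[a] + state.p_mod[b])
                - _h(state.q_mod[a] + state.p_mod[a])
                - _h(state.q_mod[b] + state.p_mod[b])
            )
            if dL < best[0] - 1e-12:
                best = (dL, (a, b))
        if best[1] is not None:
            a, b = best[1]
            for i in range(n):
                if state.module[i] == b:
                    links = state.node_to_module_weights(i)
                    state.apply_move(i, a, links)
            improved = True

    # single-node refinement sweeps in random order
    moved = True
    while moved:
        moved = False
        order = rng.permutation(n)
        for i in order:
            links = state.node_to_module_weights(int(i))
            candidates = sorted(links)
            src = int(state.module[i])
            best_dL, best_m = -1e-12, src
            for m in candidates:
                if m == src:
                    continue
                dL = state.delta_move(int(i), m, links)
                if dL < best_dL:
                    best_dL, best_m = dL, m
            if best_m != src:
                state.apply_move(int(i), best_m, links)
                moved = True

    return {nodes[i]: int(state.module[i]) for i in range(n)}


def detect_clusters(graph: nx.Graph, seed: int = 0, n_restarts: int = 8) -> Partition:
    """Minimize the two-level map equation; best of ``n_restarts`` seeded runs.

    Connected components are optimized independently and never merged;
    isolated (zero-strength) nodes become singleton clusters.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(seed)
    assignment: dict = {}
    next_id = 0
    for comp in sorted(nx.connected_components(graph), key=lambda c: sorted(map(str, c))):
        nodes = sorted(comp, key=str)
        if len(nodes) == 1 or sum(dict(graph.degree(nodes, weight="weight")).values()) == 0:
            for v in nodes:
                assignment[v] = next_id
                next_id += 1
            continue
        sub_best: dict | None = None
        best_L = math.inf
        for _ in range(max(1, n_restarts)):
            cand = _optimize_component(graph, nodes, rng)
            L = map_equation(graph.subgraph(nodes), cand)
            if L < best_L - 1e-12:
                best_L, sub_best = L, cand
        # relabel this component's modules contiguously
        remap: dict[int, int] = {}
        for v in nodes:
            m = sub_best[v]
            if m not in remap:
                remap[m] = next_id
                next_id += 1
            assignment[v] = remap[m]
        next_id = max(assignment.values()) + 1

    positive = [v for v in graph if graph.degree(v, weight="weight") > 0]
    L_total = map_equation(graph.subgraph(positive), {v: assignment[v] for v in positive}) if positive else 0.0
    # contiguous ids in node-sorted order
    final: dict[int, int] = {}
    out = {}
    for v in sorted(graph.nodes, key=str):
        m = assignment[v]
        if m not in final:
            final[m] = len(final)
        out[v] = final[m]
    return Partition(assignment=out, codelength=L_total)


def singleton_partition(graph: nx.Graph) -> dict:
    return {v: i for i, v in enumerate(sorted(graph.nodes, key=str))}


def one_module_partition(graph: nx.Graph) -> dict:
    return {v: 0 for v in graph.nodes}
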