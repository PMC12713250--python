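"""Weighted Newman-Girvan modularity and a from-scratch Louvain algorithm.

Modularity of a partition of an undirected weighted graph is

    Q = (1 / 2m) * sum_ij [A_ij - k_i k_j / (2m)] * delta(c_i, c_j)

with A the (weighted) adjacency matrix, k_i the weighted degree and
2m the total degree.  Self-loops follow the convention A_ii = 2 w_ii so
that aggregation (collapsing communities into super-nodes whose
self-loop carries the intra-community weight) preserves Q exactly.

The Louvain algorithm alternates a local node-movement stage (greedy
modularity-gain moves) with a network-aggregation stage, repeating until
modularity no longer improves.  An exhaustive set-partition enumeration
is provided as an oracle for small graphs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "Partition",
    "LouvainResult",
    "modularity",
    "louvain",
    "aggregate_graph",
    "exhaustive_best_partition",
]


@dataclass
class Partition:
    """Node -> community assignment with its modularity."""

    assignment: dict
    modularity: float
    level: int = 0

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class LouvainResult:
    levels: list[Partition]

    @property
    def final(self) -> Partition:
        return self.levels[-1]


def _degrees(graph: nx.Graph) -> tuple[dict, float]:
    """Weighted degrees (self-loops counted twice) and total degree 2m."""
    k = {u: 0.0 for u in graph.nodes}
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError(f"negative edge weight on ({u!r}, {v!r})")
        if u == v:
            k[u] += 2.0 * w
        else:
            k[u] += w
            k[v] += w
    return k, sum(k.values())


def modularity(graph: nx.Graph, assignment: dict) -> float:
    """Weighted Newman-Girvan modularity of ``assignment`` on ``graph``."""
    if graph.number_of_nodes() == 0:
        raise ValueError("modularity of an empty graph is undefined")
    missing = [u for u in graph.nodes if u not in assignment]
    if missing:
        raise ValueError(f"nodes without community assignment: {missing[:5]}")
    k, m2 = _degrees(graph)
    if m2 <= 0:
        raise ValueError("graph total weight must be positive")
    s_in: dict = {}
    s_tot: dict = {}
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if assignment[u] == assignment[v]:
            s_in[assignment[u]] = s_in.get(assignment[u], 0.0) + 2.0 * w
    for u in graph.nodes:
        c = assignment[u]
        s_tot[c] = s_tot.get(c, 0.0) + k[u]
    return sum(
        s_in.get(c, 0.0) / m2 - (s_tot[c] / m2) ** 2 for c in s_tot
    )


def aggregate_graph(graph: nx.Graph, assignment: dict) -> nx.Graph:
    """Collapse communities into super-nodes; intra-community weight
    (edges plus existing self-loops) becomes the super-node's self-loop,
    so modularity of the induced identity partition equals modularity of
    the flattened partition on the original graph."""
    agg = nx.Graph()
    agg.add_nodes_from(set(assignment[u] for u in graph.nodes))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        cu, cv = assignment[u], assignment[v]
        if agg.has_edge(cu, cv):
            agg[cu][cv]["weight"] += w
        else:
            agg.add_edge(cu, cv, weight=w)
    return agg


def _local_move(adj: list[dict], k: np.ndarray, m2: float,
                order: np.ndarray, min_gain: float) -> np.ndarray:
    """One local-movement stage on an integer-indexed graph.

    ``adj[u]`` maps neighbour -> weight (no self entries); returns the
    community index per node.  Ties in modularity gain break toward the
    lowest community identifier.
    """
    n = len(adj)
    node2c = np.arange(n)
    s_tot = k.copy()
    improved = True
    while improved:
        improved = False
        for u in order:
            c_old = node2c[u]
            s_tot[c_old] -= k[u]
            links: dict[int, float] = {}
            for v, w in adj[u].items():
                c = node2c[v]
                links[c] = links.get(c, 0.0) + w
            best_c, best_score = c_old, links.get(c_old, 0.0) - s_tot[c_old] * k[u] / m2
            for c in sorted(links):
                score = links[c] - s_tot[c] * k[u] / m2
                if score > best_score + 1e-15 or (
                        abs(score - best_score) <= 1e-15 and c < best_c):
                    best_c, best_score = c, score
            old_score = links.get(c_old, 0.0) - s_tot[c_old] * k[u] / m2
            if best_c != c_old and (best_score - old_score) > min_gain * m2 / 2.0:
                node2c[u] = best_c
                improved = True
            s_tot[node2c[u]] += k[u]
    return node2c


def louvain(graph: nx.Graph, seed: int | None = 0,
            min_gain: float = 1e-9) -> LouvainResult:
    """Two-stage Louvain modularity maximization.

    Runs local node movement and network aggregation until modularity no
    longer improves by more than ``min_gain``.  Node sweep order is the
    sorted node list, shuffled by ``seed`` (``seed=None`` keeps sorted
    order); deterministic for a given seed.  One :class:`Partition` per
    aggregation round is recorded; modularity never decreases across
    levels.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot run Louvain on an empty graph")
    nodes = sorted(graph.nodes, key=str)
    index = {u: i for i, u in enumerate(nodes)}
    _, m2 = _degrees(graph)
    if m2 <= 0:
        raise ValueError("graph total weight must be positive")

    # integer-indexed working graph: adjacency dicts + self-loop weights
    n = len(nodes)
    adj: list[dict] = [dict() for _ in range(n)]
    loops = np.zeros(n)
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError(f"negative edge weight on ({u!r}, {v!r})")
        iu, iv = index[u], index[v]
        if iu == iv:
            loops[iu] += w
        else:
            adj[iu][iv] = adj[iu].get(iv, 0.0) + w
            adj[iv][iu] = adj[iv].get(iu, 0.0) + w

    rng = np.random.default_rng(seed) if seed is not None else None
    flat = {u: index[u] for u in nodes}       # original node -> work index
    levels: list[Partition] = []
    prev_q = -np.inf

    while True:
        n_work = len(adj)
        k = np.array([sum(a.values()) + 2.0 * loops[i]
                      for i, a in enumerate(adj)])
        order = np.arange(n_work)
        if rng is not None:
            rng.shuffle(order)
        node2c = _local_move(adj, k, m2, order, min_gain)

        # relabel communities 0..K-1 in order of lowest member index
        labels = {}
        for i in range(n_work):
            c = node2c[i]
            if c not in labels:
                labels[c] = len(labels)
        node2c = np.array([labels[c] for c in node2c])
        n_comm = len(labels)

        new_flat = {u: int(node2c[flat[u]]) for u in nodes}
        q = modularity(graph, new_flat)
        if levels and q <= prev_q + min_gain:
            break
        levels.append(Partition(assignment=new_flat, modularity=q,
                                level=len(levels)))
        flat = new_flat
        prev_q = q
        if n_comm == n_work:
            break

        # aggregation stage
        new_adj: list[dict] = [dict() for _ in range(n_comm)]
        new_loops = np.zeros(n_comm)
        for i in range(n_work):
            ci = node2c[i]
            new_loops[ci] += loops[i]
            for j, w in adj[i].items():
                if j < i:
                    continue
                cj = node2c[j]
                if ci == cj:
                    new_loops[ci] += w
                else:
                    new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                    new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
        adj, loops = new_adj, new_loops

    if not levels:    # no move ever improved: singleton partition
        assignment = {u: index[u] for u in nodes}
        levels.append(Partition(assignment=assignment,
                                modularity=modularity(graph, assignment),
                                level=0))
    return LouvainResult(levels=levels)


def _set_partitions(n: int):
    """Yield all set partitions of range(n) as lists of blocks (indices)."""
    if n == 0:
        yield []
        return

    def rec(i: int, blocks: list[list[int]]):
        if i == n:
            yield [list(b) for b in blocks]
            return
        for b in blocks:
            b.append(i)
            yield from rec(i + 1, blocks)
            b.pop()
        blocks.append([i])
        yield from rec(i + 1, blocks)
        blocks.pop()

    yield from rec(0, [])


def exhaustive_best_partition(graph: nx.Graph, max_nodes: int = 12) -> Partition:
    """Global maximum-modularity partition by full set-partition search.

    A test oracle: refuses graphs with more than ``max_nodes`` nodes
    (the Bell number explodes) and graphs with zero total weight.
    """
    nodes = sorted(graph.nodes, key=str)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    if n > max_nodes:
        raise ValueError(
            f"exhaustive search refused for {n} > {max_nodes} nodes")
    k, m2 = _degrees(graph)
    if m2 <= 0:
        raise ValueError("graph total weight must be positive")
    A = np.zeros((n, n))
    idx = {u: i for i, u in enumerate(nodes)}
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if u == v:
            A[idx[u], idx[u]] += 2.0 * w
        else:
            A[idx[u], idx[v]] += w
            A[idx[v], idx[u]] += w
    kv = [float(k[u]) for u in nodes]
    Al = A.tolist()

    # depth-first over set partitions with incrementally maintained
    # per-block adjacency and degree sums, so each leaf costs O(#blocks)
    best: list = [-np.inf, None]
    blocks: list[list[int]] = []
    a_sums: list[float] = []
    k_sums: list[float] = []

    def rec(i: int) -> None:
        if i == n:
            q = sum(a / m2 - (ks / m2) ** 2
                    for a, ks in zip(a_sums, k_sums))
            if q > best[0] + 1e-15:
                best[0] = q
                best[1] = [list(b) for b in blocks]
            return
        row = Al[i]
        for bi, b in enumerate(blocks):
            da = 2.0 * sum(row[j] for j in b) + row[i]
            b.append(i)
            a_sums[bi] += da
            k_sums[bi] += kv[i]
            rec(i + 1)
            b.pop()
            a_sums[bi] -= da
            k_sums[bi] -= kv[i]
        blocks.append([i])
        a_sums.append(row[i])
        k_sums.append(kv[i])
        rec(i + 1)
        blocks.pop()
        a_sums.pop()
        k_sums.pop()

    rec(0)
    best_q, best_blocks = best
    assignment = {}
    for c, b in enumerate(best_blocks):
        for i in b:
            assignment[nodes[i]] = c
    return Partition(assignment=assignment, modularity=best_q, level=0)
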