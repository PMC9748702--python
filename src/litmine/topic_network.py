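"""Topic co-occurrence networks and community structure.

Each document contributes its two highest-probability topics: the top-1
("primary") topic determines node sizes, and the unordered top-2 pair
increments one edge weight.  Communities are found by greedy modularity
maximization (Louvain's two-phase scheme: local node moves to the best
positive gain, then aggregation of communities into super-nodes, iterated
to a fixed point).  Both the modularity score and the optimizer are
implemented here from first principles; the graph container is a
:class:`networkx.Graph` for interoperability (GEXF/GraphML export for
Gephi-style tooling).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "TopicAssignment",
    "Communities",
    "top2_assignments",
    "build_cooccurrence_graph",
    "modularity",
    "louvain",
    "export_graph",
    "read_graph",
]


@dataclass(frozen=True)
class TopicAssignment:
    """Per-document topic ranking: primary topic and the top-2 pair
    (stored with the smaller index first; ``None`` when K == 1)."""

    doc_id: str
    primary: int
    pair: tuple[int, int] | None
    probabilities: tuple[float, ...]


def top2_assignments(
    theta: np.ndarray,
    doc_ids: list[str] | None = None,
    atol: float = 1e-8,
) -> list[TopicAssignment]:
    """Extract each document's two highest-probability topics.

    Ties are broken by the lowest topic index (stable argsort on the
    negated row).  Rows must be stochastic within ``atol``.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2:
        raise ValueError("theta must be 2-D (docs x topics)")
    if (theta < -atol).any() or not np.allclose(theta.sum(axis=1), 1.0, atol=atol):
        raise ValueError("theta rows must be nonnegative and sum to 1")
    n_docs, K = theta.shape
    if doc_ids is None:
        doc_ids = [str(d) for d in range(n_docs)]
    out = []
    for d in range(n_docs):
        order = np.argsort(-theta[d], kind="stable")
        primary = int(order[0])
        if K >= 2:
            second = int(order[1])
            pair = (min(primary, second), max(primary, second))
            probs = (float(theta[d, primary]), float(theta[d, second]))
        else:
            pair = None
            probs = (float(theta[d, primary]),)
        out.append(TopicAssignment(doc_id=doc_ids[d], primary=primary,
                                   pair=pair, probabilities=probs))
    return out


def build_cooccurrence_graph(
    assignments: list[TopicAssignment],
    n_topics: int | None = None,
) -> nx.Graph:
    """Weighted topic graph: edge (j, k) counts documents whose top-2 set
    is {j, k}; node attribute ``size`` counts primary-topic documents.

    With ``n_topics`` given, all topics appear as nodes even when
    documentless; otherwise only topics observed in the assignments do.
    """
    graph = nx.Graph()
    if n_topics is not None:
        graph.add_nodes_from(range(n_topics), size=0)
    for a in assignments:
        if a.primary not in graph:
            graph.add_node(a.primary, size=0)
        graph.nodes[a.primary]["size"] += 1
        if a.pair is None:
            continue
        j, k = a.pair
        for node in (j, k):
            if node not in graph:
                graph.add_node(node, size=0)
        if graph.has_edge(j, k):
            graph[j][k]["weight"] += 1
        else:
            graph.add_edge(j, k, weight=1)
    return graph


def modularity(
    graph: nx.Graph,
    partition: dict,
    resolution: float = 1.0,
) -> float:
    """Weighted Newman-Girvan modularity of a partition.

    Q = sum_c [ Sigma_in / 2m - resolution * (Sigma_tot / 2m)^2 ], where
    Sigma_in counts both endpoints of intra-community edges (self-loops
    twice) and Sigma_tot sums community degrees.
    """
    m2 = 0.0  # 2m
    for u, v, w in graph.edges(data="weight", default=1.0):
        m2 += 2.0 * w
    if m2 <= 0:
        raise ValueError("modularity undefined for a graph with zero total weight")
    missing = [n for n in graph.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition misses nodes: {missing[:5]}")
    sigma_in: dict = {}
    sigma_tot: dict = {}
    for node in graph.nodes:
        c = partition[node]
        deg = sum(w * (2.0 if u == node and v == node else 1.0)
                  for u, v, w in graph.edges(node, data="weight", default=1.0))
        sigma_tot[c] = sigma_tot.get(c, 0.0) + deg
    for u, v, w in graph.edges(data="weight", default=1.0):
        if partition[u] == partition[v]:
            sigma_in[partition[u]] = sigma_in.get(partition[u], 0.0) + 2.0 * w
    q = 0.0
    for c, tot in sigma_tot.items():
        q += sigma_in.get(c, 0.0) / m2 - resolution * (tot / m2) ** 2
    return q


@dataclass
class Communities:
    """Node -> community map plus the modularity of that partition,
    recomputed from the definition on the original graph."""

    membership: dict
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


def _local_moves(adj, degree, m2, order, resolution):
    """Phase one: greedily move nodes to the neighboring community with
    the largest positive modularity gain until no move helps.  Gain ties
    are broken by the lowest community id."""
    community = {u: u for u in order}
    comm_tot = {u: degree[u] for u in order}
    improved_any = False
    moved = True
    while moved:
        moved = False
        for u in order:
            c_old = community[u]
            k_u = degree[u]
            # weight from u to each neighboring community (self-loops excluded)
            w_to: dict = {}
            for v, w in adj[u].items():
                if v == u:
                    continue
                w_to[community[v]] = w_to.get(community[v], 0.0) + w
            comm_tot[c_old] -= k_u
            best_c, best_gain = c_old, w_to.get(c_old, 0.0) - resolution * comm_tot[c_old] * k_u / m2
            for c in sorted(w_to):
                if c == c_old:
                    continue
                gain = w_to[c] - resolution * comm_tot[c] * k_u / m2
                if gain > best_gain + 1e-12 or (
                    abs(gain - best_gain) <= 1e-12 and c < best_c
                ):
                    best_c, best_gain = c, gain
            community[u] = best_c
            comm_tot[best_c] += k_u
            if best_c != c_old:
                moved = True
                improved_any = True
    return community, improved_any


def louvain(
    graph: nx.Graph,
    resolution: float = 1.0,
    seed: int | None = 0,
    shuffle: bool = True,
    n_restarts: int = 50,
) -> Communities:
    """Two-phase greedy modularity optimization with seeded restarts.

    The first pass visits nodes in ascending order; subsequent restarts
    (when ``shuffle`` is on) use visit orders drawn from a generator
    seeded with ``seed``, and the partition with the highest Q wins (ties
    keep the earlier one).  The result is deterministic for a given seed.
    The reported Q is recomputed from the definition on the input graph.
    The optimizer remains greedy: restarts make it exact on the small
    instances exercised in the test suite, but it carries no general
    optimality guarantee.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("louvain requires a nonempty graph")
    rng = np.random.default_rng(seed)
    n_runs = max(1, n_restarts) if shuffle else 1
    best: Communities | None = None
    for run in range(n_runs):
        membership = _louvain_once(graph, resolution,
                                   rng if run > 0 else None)
        q = modularity(graph, membership, resolution=resolution)
        if best is None or q > best.modularity + 1e-15:
            best = Communities(membership=membership, modularity=q)
    return best


def _louvain_once(graph: nx.Graph, resolution: float, order_rng) -> dict:
    """One greedy two-phase run; ``order_rng`` permutes visit orders
    (None keeps deterministic ascending order)."""
    nodes = sorted(graph.nodes)
    # current partition of the ORIGINAL nodes
    membership = {u: i for i, u in enumerate(nodes)}
    # working aggregated graph: community-indexed adjacency
    adj = {membership[u]: {} for u in nodes}
    for u, v, w in graph.edges(data="weight", default=1.0):
        iu, iv = membership[u], membership[v]
        adj[iu][iv] = adj[iu].get(iv, 0.0) + (2.0 * w if iu == iv else w)
        if iu != iv:
            adj[iv][iu] = adj[iv].get(iu, 0.0) + w
    while True:
        order = sorted(adj)
        if order_rng is not None:
            order = [order[i] for i in order_rng.permutation(len(order))]
        degree = {u: sum(adj[u].values()) for u in adj}  # self-loops already doubled
        m2 = sum(degree.values())
        if m2 <= 0:
            break
        community, improved = _local_moves(adj, degree, m2, order, resolution)
        if not improved:
            break
        # relabel communities compactly, in order of first appearance
        labels: dict = {}
        for u in sorted(community):
            labels.setdefault(community[u], len(labels))
        membership = {orig: labels[community[c]] for orig, c in membership.items()}
        # phase two: aggregate communities into super-nodes
        new_adj: dict = {c: {} for c in set(labels.values())}
        seen = set()
        for u, nbrs in adj.items():
            for v, w in nbrs.items():
                if (v, u) in seen:
                    continue
                seen.add((u, v))
                cu, cv = labels[community[u]], labels[community[v]]
                if u == v:
                    new_adj[cu][cu] = new_adj[cu].get(cu, 0.0) + w
                elif cu == cv:
                    new_adj[cu][cu] = new_adj[cu].get(cu, 0.0) + 2.0 * w
                else:
                    new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
                    new_adj[cv][cu] = new_adj[cv].get(cu, 0.0) + w
        adj = new_adj
    return membership


_FORMATS = {"gexf", "graphml"}


def export_graph(
    graph: nx.Graph,
    communities: Communities | None,
    path: str | Path,
    fmt: str = "gexf",
) -> None:
    """Write the topic graph with size/community/weight attributes.

    Supported formats: GEXF and GraphML; both re-import losslessly via
    :func:`read_graph`.
    """
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; supported: {sorted(_FORMATS)}")
    out = graph.copy()
    if communities is not None:
        for node in out.nodes:
            out.nodes[node]["community"] = int(communities.membership[node])
    if fmt == "gexf":
        nx.write_gexf(out, path)
    else:
        nx.write_graphml(out, path)


def read_graph(path: str | Path, fmt: str = "gexf") -> nx.Graph:
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; supported: {sorted(_FORMATS)}")
    raw = nx.read_gexf(path) if fmt == "gexf" else nx.read_graphml(path)
    graph = nx.Graph()
    for node, data in raw.nodes(data=True):
        attrs = {k: data[k] for k in ("size", "community") if k in data}
        graph.add_node(int(node), **{k: int(v) for k, v in attrs.items()})
    for u, v, data in raw.edges(data=True):
        graph.add_edge(int(u), int(v), weight=int(data.get("weight", 1)))
    return graph
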