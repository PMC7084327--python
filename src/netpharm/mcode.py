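"""MCODE-style molecular-complex detection on PPI networks.

The procedure follows the classic three stages of molecular complex
detection:

1. **Vertex weighting** — each node is weighted by the highest k-core of
   its closed neighborhood: weight = (core level k) x (density of that
   k-core subgraph). Densely interconnected neighborhoods produce heavy
   vertices.
2. **Complex prediction** — starting from the heaviest unvisited vertex
   (the *seed*), the cluster grows outward, admitting neighbors whose
   weight is within a fraction ``vwp`` (vertex weight percentage) of the
   seed weight. Each vertex joins at most one cluster, so clusters are
   node-disjoint.
3. **Post-processing** — an optional *haircut* trims loosely attached
   members (the 2-core of the cluster subgraph is kept); an optional
   *fluff* step grows the boundary by dense neighborhoods. Clusters that
   do not contain an internal k-core of at least ``k_core`` are discarded;
   raising ``k_core`` therefore yields fewer, tighter clusters.

Each cluster is scored by ``density x size`` with loopless density
``2E / (N(N-1))``, i.e. score = 2E/(N-1). All tie-breaks (seed selection,
growth order, output ranking) are deterministic so results do not depend
on node insertion order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import pandas as pd

__all__ = [
    "McodeParams",
    "Cluster",
    "core_number",
    "vertex_weights",
    "cluster_score",
    "find_clusters",
    "clusters_to_frame",
]


@dataclass(frozen=True)
class McodeParams:
    """Parameters of the clustering procedure.

    ``k_core``: minimum internal core a cluster must contain (>= 2).
    ``vwp``: vertex weight percentage in [0, 1); a neighbor is admitted when
    its weight >= (1 - vwp) x seed weight.
    ``haircut``: trim members not in the 2-core of the cluster subgraph.
    ``fluff``: expand the boundary with neighbors whose closed-neighborhood
    density exceeds ``fluff_density_threshold`` (fluffed clusters may
    overlap; off by default).
    """

    k_core: int = 2
    vwp: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_density_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")
        if not 0.0 <= self.vwp < 1.0:
            raise ValueError("vwp must lie in [0, 1)")


@dataclass(frozen=True)
class Cluster:
    members: frozenset
    n_nodes: int
    n_edges: int
    score: float
    seed: Optional[str]
    rank: int


def _density(n_nodes: int, n_edges: int) -> float:
    # loopless density 2E/(N(N-1)); a single node has density 0
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def core_number(net: nx.Graph) -> dict:
    """Core number of every node by iterative peeling.

    The core number of a node is the largest k such that the node belongs
    to the k-core (the maximal subgraph of minimum degree k). Implemented
    as repeated removal of minimum-degree vertices.
    """
    degrees = {n: d for n, d in net.degree()}
    neighbors = {n: set(net.neighbors(n)) - {n} for n in net.nodes}
    core: dict = {}
    remaining = set(degrees)
    k = 0
    while remaining:
        node = min(remaining, key=lambda n: (degrees[n], n))
        k = max(k, degrees[node])
        core[node] = k
        remaining.remove(node)
        for nb in neighbors[node] & remaining:
            degrees[nb] -= 1
    return core


def _highest_kcore_subgraph(net: nx.Graph) -> tuple[int, set]:
    """(k, nodes) of the maximum-k k-core of ``net`` (k=0 for edgeless)."""
    core = core_number(net)
    if not core:
        return 0, set()
    k = max(core.values())
    return k, {n for n, c in core.items() if c == k}


def vertex_weights(net: nx.Graph) -> dict:
    """MCODE vertex weighting.

    For each node v, take the subgraph induced on the closed neighborhood
    N[v], find its highest k-core, and set
    weight(v) = k x density(highest k-core). Isolated nodes weigh 0.
    """
    weights: dict = {}
    for v in net.nodes:
        nbhd = set(net.neighbors(v)) | {v}
        sub = net.subgraph(nbhd)
        k, core_nodes = _highest_kcore_subgraph(sub)
        if k == 0:
            weights[v] = 0.0
            continue
        core_sub = sub.subgraph(core_nodes)
        weights[v] = k * _density(core_sub.number_of_nodes(), core_sub.number_of_edges())
    return weights


def cluster_score(n_nodes: int, n_edges: int) -> float:
    """Density x size score of a cluster: (2E / (N(N-1))) x N = 2E/(N-1)."""
    if n_nodes < 2:
        raise ValueError("cluster score requires at least 2 nodes")
    if n_edges < 0 or n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValueError("edge count inconsistent with a simple graph")
    return _density(n_nodes, n_edges) * n_nodes


def _grow_cluster(net: nx.Graph, seed, weights: dict, vwp: float, visited: set) -> set:
    threshold = weights[seed] * (1.0 - vwp)
    members = {seed}
    frontier = [seed]
    while frontier:
        current = frontier.pop()
        for nb in sorted(net.neighbors(current)):
            if nb in members or nb in visited:
                continue
            if weights[nb] >= threshold:
                members.add(nb)
                frontier.append(nb)
    return members


def _haircut(net: nx.Graph, members: set) -> set:
    """Keep the 2-core of the cluster subgraph (iteratively shed degree-1 nodes)."""
    sub = net.subgraph(members)
    core = core_number(sub)
    return {n for n, c in core.items() if c >= 2}


def _fluff(net: nx.Graph, members: set, density_threshold: float) -> set:
    extra = set()
    boundary = set()
    for m in members:
        boundary |= set(net.neighbors(m))
    for nb in sorted(boundary - members):
        nbhd = set(net.neighbors(nb)) | {nb}
        sub = net.subgraph(nbhd)
        if _density(sub.number_of_nodes(), sub.number_of_edges()) > density_threshold:
            extra.add(nb)
    return members | extra


def find_clusters(net: nx.Graph, params: Optional[McodeParams] = None) -> list[Cluster]:
    """Detect dense clusters by seeded greedy growth.

    Seeds are taken in order of decreasing vertex weight (ties by node id).
    Grown clusters are haircut/fluffed per ``params``, then discarded unless
    their subgraph contains a ``k_core``-core. The output is sorted by
    score descending (ties: larger size, then lexicographically smallest
    member) and ranked from 1.
    """
    params = params or McodeParams()
    weights = vertex_weights(net)
    visited: set = set()
    raw: list[tuple[set, object]] = []
    for seed in sorted(net.nodes, key=lambda n: (-weights[n], str(n))):
        if seed in visited or weights[seed] <= 0.0:
            continue
        members = _grow_cluster(net, seed, weights, params.vwp, visited)
        visited |= members
        if params.haircut:
            members = _haircut(net, members)
        if params.fluff:
            members = _fluff(net, members, params.fluff_density_threshold)
        if not members:
            continue
        raw.append((members, seed if seed in members else None))

    clusters = []
    for members, seed in raw:
        sub = net.subgraph(members)
        max_core, _ = _highest_kcore_subgraph(sub)
        if max_core < params.k_core:
            continue
        n, e = sub.number_of_nodes(), sub.number_of_edges()
        clusters.append((members, n, e, cluster_score(n, e), seed))

    clusters.sort(key=lambda c: (-c[3], -c[1], min(str(m) for m in c[0])))
    return [
        Cluster(
            members=frozenset(members),
            n_nodes=n,
            n_edges=e,
            score=score,
            seed=seed,
            rank=rank,
        )
        for rank, (members, n, e, score, seed) in enumerate(clusters, start=1)
    ]


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    """Tabulate clusters (rank, score, nodes, edges, seed, member list)."""
    return pd.DataFrame(
        {
            "rank": [c.rank for c in clusters],
            "score": [c.score for c in clusters],
            "nodes": [c.n_nodes for c in clusters],
            "edges": [c.n_edges for c in clusters],
            "seed": [c.seed for c in clusters],
            "members": [",".join(sorted(c.members)) for c in clusters],
        }
    )
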