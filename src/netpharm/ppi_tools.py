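"""Protein-protein interaction (PPI) tables: loading, filtering, hubs, overlap.

Edge tables follow the STRING export dialect (``node1``, ``node2``,
``combined_score``). Scores may be on either the 0-1 or the 0-1000 scale;
the dialect is auto-detected (any score above 1 implies the 0-1000 scale)
and normalized to 0-1 before the confidence cutoff is applied. Cleaning
drops self-loops, duplicate undirected edges, and nodes left isolated by
the filter.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Union

import networkx as nx
import pandas as pd

__all__ = ["load_ppi", "degree_ranking", "intersect_subnetwork"]

from .target_network import normalize_symbol


def _read_edge_frame(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t")
    required = {"node1", "node2", "combined_score"}
    if not required <= set(df.columns):
        if df.shape[1] >= 3:
            df = df.iloc[:, :3].copy()
            df.columns = ["node1", "node2", "combined_score"]
        else:
            raise ValueError(
                f"PPI table needs columns node1, node2, combined_score; got {list(df.columns)}"
            )
    return df


def load_ppi(source, min_confidence: float = 0.7) -> nx.Graph:
    """Load a STRING-dialect edge table into a cleaned, score-filtered graph.

    Malformed rows raise with their (1-based, header-exclusive) line number.
    Mixing fractional 0-1 scores with 0-1000 integer scores in one table is
    rejected as ambiguous. Duplicate (u, v)/(v, u) rows keep the maximum
    score. Nodes are typed ``kind='protein'``.
    """
    if not 0 <= min_confidence <= 1:
        raise ValueError("min_confidence must lie in [0, 1]")
    df = _read_edge_frame(source)
    for offset, row in enumerate(df.itertuples(index=False), start=1):
        u, v, s = row
        if pd.isna(u) or pd.isna(v) or str(u).strip() == "" or str(v).strip() == "":
            raise ValueError(f"malformed PPI row at line {offset}: empty node id")
        try:
            s = float(s)
        except (TypeError, ValueError):
            raise ValueError(f"malformed PPI row at line {offset}: bad score {s!r}") from None
        if pd.isna(s) or s < 0:
            raise ValueError(f"malformed PPI row at line {offset}: bad score {s!r}")
    scores = df["combined_score"].astype(float)
    if (scores > 1000).any():
        raise ValueError("combined_score above 1000: not a known dialect")
    if (scores > 1).any():
        if ((scores > 0) & (scores < 1)).any():
            raise ValueError("mixed 0-1 and 0-1000 score dialects in one table")
        scores = scores / 1000.0

    best: dict[tuple[str, str], float] = {}
    for (u, v), s in zip(zip(df["node1"], df["node2"]), scores):
        u, v = normalize_symbol(u), normalize_symbol(v)
        if u == v:
            continue  # self-loop
        key = (u, v) if u <= v else (v, u)
        if s >= min_confidence:
            best[key] = max(best.get(key, 0.0), float(s))
    g = nx.Graph()
    for (u, v), s in sorted(best.items()):
        g.add_node(u, kind="protein")
        g.add_node(v, kind="protein")
        g.add_edge(u, v, score=s)
    return g


def degree_ranking(net: nx.Graph, k: int) -> list[tuple[str, int]]:
    """Top-``k`` nodes by degree, ties broken lexicographically by node id."""
    if k <= 0:
        raise ValueError("k must be positive")
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    ranked = sorted(net.degree(), key=lambda item: (-item[1], item[0]))
    return [(n, int(d)) for n, d in ranked[:k]]


def intersect_subnetwork(
    herb_targets: Iterable[str],
    disease_targets: Iterable[str],
    ppi: nx.Graph,
) -> tuple[nx.Graph, dict]:
    """Induce the PPI subnetwork on the herb/disease target overlap.

    Both input sets are symbol-normalized. Returns the induced subgraph
    (nodes = overlap genes present in the PPI, edges = PPI edges with both
    endpoints in the overlap) together with Venn counts
    ``{'a_only', 'b_only', 'both'}``. An empty overlap yields an empty
    graph, not an error.
    """
    a = {normalize_symbol(t) for t in herb_targets}
    b = {normalize_symbol(t) for t in disease_targets}
    both = a & b
    venn = {"a_only": len(a - b), "b_only": len(b - a), "both": len(both)}
    sub = ppi.subgraph(both & set(ppi.nodes)).copy()
    return sub, venn
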