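"""Synthetic pipeline inputs with known ground truth.

Every analysis stage has a matching generator so the whole pipeline is
testable offline: component property tables with known pass/fail labels,
component-target association tables, sparse background interaction graphs
with planted cliques (an unambiguous dense-module ground truth for the
clustering stage), and gene-set collections with one planted enriched set.
All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GeneSet

__all__ = [
    "gen_components",
    "gen_associations",
    "gen_planted_graph",
    "planted_graph_to_edge_table",
    "gen_genesets",
]

_FAIL_MODES = ("ob", "caco2", "dl", "gi", "lipinski")


def gen_components(
    n: int, pass_fraction: float = 0.5, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Component property table with known strict-pass labels.

    Descriptors are drawn uniformly from ranges spanning those of typical
    herb constituents (MW 150-500 Da, AlogP -1-5, OB 10-90 %, Caco-2
    -1.5-1, DL 0-0.8). ``round(n * pass_fraction)`` rows are constructed to
    satisfy all five strict criteria; each remaining row violates exactly
    one randomly chosen criterion (for the Lipinski mode, two rule-of-five
    conditions are broken so a single tolerated violation cannot rescue
    it). Returns the table plus a boolean label series aligned on id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= pass_fraction <= 1.0:
        raise ValueError("pass_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pass = int(round(n * pass_fraction))
    labels = np.zeros(n, dtype=bool)
    labels[rng.permutation(n)[:n_pass]] = True

    rows = []
    for i in range(n):
        row = {
            "id": f"SC{i:03d}",
            "name": f"synthetic-compound-{i}",
            "MW": round(rng.uniform(150, 500), 2),
            "AlogP": round(rng.uniform(-1, 5), 2),
            "nHdon": int(rng.integers(0, 6)),
            "nHacc": int(rng.integers(0, 11)),
            "TPSA": round(rng.uniform(20, 140), 2),
            "RBN": int(rng.integers(0, 11)),
            "OB": round(rng.uniform(30, 90), 2),
            "Caco2": round(rng.uniform(-0.39, 1.0), 2),
            "DL": round(rng.uniform(0.18, 0.8), 2),
            "GI": "High",
        }
        if not labels[i]:
            mode = _FAIL_MODES[rng.integers(len(_FAIL_MODES))]
            if mode == "ob":
                row["OB"] = round(rng.uniform(10, 29.9), 2)
            elif mode == "caco2":
                row["Caco2"] = round(rng.uniform(-1.5, -0.45), 2)
            elif mode == "dl":
                row["DL"] = round(rng.uniform(0.0, 0.17), 2)
            elif mode == "gi":
                row["GI"] = "Low"
            else:  # two rule-of-five violations
                row["MW"] = round(rng.uniform(520, 700), 2)
                row["AlogP"] = round(rng.uniform(5.5, 7.0), 2)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df, pd.Series(labels, index=df["id"], name="strict_pass")


def gen_associations(
    component_ids: Sequence[str],
    gene_pool: Sequence[str],
    targets_per_component: tuple[int, int] = (10, 30),
    seed: int = 0,
) -> pd.DataFrame:
    """Component-target association table mixing identified and predicted rows.

    For each component a uniform number of targets is sampled from the gene
    pool; each association is assigned a source (identified / hitpick /
    sea) and, for predictions, a score uniform on [0.3, 1) so that roughly
    the upper seven tenths survive the conventional 0.5 cutoffs.
    """
    rng = np.random.default_rng(seed)
    lo, hi = targets_per_component
    pool = list(gene_pool)
    rows = []
    for comp in component_ids:
        n_t = int(rng.integers(lo, hi + 1))
        targets = rng.choice(pool, size=min(n_t, len(pool)), replace=False)
        for t in targets:
            source = ["identified", "hitpick", "sea"][rng.choice(3, p=[0.5, 0.2, 0.3])]
            score = np.nan if source == "identified" else round(float(rng.uniform(0.3, 1.0)), 3)
            rows.append(
                {"component_id": comp, "target": str(t), "source": source, "score": score}
            )
    return pd.DataFrame(rows, columns=["component_id", "target", "source", "score"])


def gen_planted_graph(
    n_background: int,
    p_background: float,
    module_sizes: Sequence[int],
    seed: int = 0,
) -> tuple[nx.Graph, dict]:
    """Erdos-Renyi background plus vertex-disjoint planted cliques.

    Background nodes ``B000..`` form G(n, p); each module adds fresh nodes
    ``M<j>N<i>`` wired as a complete clique (density 1 maximizes the
    density x size cluster score, so recovery is unambiguous). Returns the
    graph and the module-membership ground truth.
    """
    if any(s < 3 for s in module_sizes):
        raise ValueError("module sizes must be >= 3")
    if not 0.0 <= p_background <= 1.0:
        raise ValueError("p_background must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    background = [f"B{i:03d}" for i in range(n_background)]
    g.add_nodes_from(background)
    for i in range(n_background):
        for j in range(i + 1, n_background):
            if rng.random() < p_background:
                g.add_edge(background[i], background[j])
    truth = {}
    for m, size in enumerate(module_sizes):
        members = [f"M{m:02d}N{i:02d}" for i in range(size)]
        for i in range(size):
            for j in range(i + 1, size):
                g.add_edge(members[i], members[j])
        truth[f"M{m:02d}"] = frozenset(members)
    return g, truth


def planted_graph_to_edge_table(g: nx.Graph, score: int = 990) -> pd.DataFrame:
    """Serialize a graph as a STRING-dialect edge table (0-1000 scores)."""
    rows = [
        {"node1": u, "node2": v, "combined_score": score}
        for u, v in sorted(map(lambda e: tuple(sorted(e)), g.edges()))
    ]
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


def gen_genesets(
    n_sets: int,
    set_size_range: tuple[int, int],
    background_size: int,
    query_size: int,
    planted_overlap: int,
    seed: int = 0,
) -> tuple[list[GeneSet], list[str], str]:
    """Gene-set collection with one planted enriched set.

    Decoy sets are sampled uniformly from the background (their overlap
    with the query follows the hypergeometric null); the designated set
    shares exactly ``planted_overlap`` genes with the query, the remainder
    drawn from outside it. Returns (sets, query, planted set id).
    """
    lo, hi = set_size_range
    if not (1 <= lo <= hi <= background_size):
        raise ValueError("invalid set size range")
    if query_size > background_size:
        raise ValueError("query larger than background")
    if planted_overlap > min(query_size, hi):
        raise ValueError("planted overlap infeasible for the given sizes")
    rng = np.random.default_rng(seed)
    background = [f"G{i:05d}" for i in range(background_size)]
    query = sorted(rng.choice(background, size=query_size, replace=False))
    non_query = sorted(set(background) - set(query))

    planted_size = int(rng.integers(max(lo, planted_overlap), hi + 1))
    members = list(rng.choice(query, size=planted_overlap, replace=False)) + list(
        rng.choice(non_query, size=planted_size - planted_overlap, replace=False)
    )
    planted_id = "SET000"
    sets = [GeneSet(set_id=planted_id, name="planted", genes=frozenset(members))]
    for i in range(1, n_sets):
        size = int(rng.integers(lo, hi + 1))
        decoy = rng.choice(background, size=size, replace=False)
        sets.append(GeneSet(set_id=f"SET{i:03d}", name=f"decoy-{i}", genes=frozenset(decoy)))
    return sets, list(query), planted_id
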