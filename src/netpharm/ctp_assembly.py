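"""Target-pathway and component-target-pathway network assembly.

Enriched pathways and their hit genes form a bipartite target-pathway (T-P)
graph; merging it with the component-target (C-T) graph over the shared
target namespace yields the tripartite component-target-pathway (C-T-P)
network used to read off which compound acts on which pathway through which
protein. Exporters cover the plain-text formats Cytoscape and friends
ingest (SIF, GraphML, edge TSV).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd

from .target_network import normalize_symbol

__all__ = [
    "read_pathway_table",
    "build_tp_network",
    "build_ctp_network",
    "export_network",
    "read_network",
]

FORMATS = ("sif", "graphml", "tsv")


def read_pathway_table(path, synonyms: Optional[dict] = None) -> pd.DataFrame:
    """Read a pathway table with slash-separated member gene lists.

    Expected tab-separated columns: ``id``, ``pathway``, optional
    ``p_value``/``p_adjust``/``count``, and ``genes`` with members joined by
    "/". Gene tokens are stripped, uppercased and passed through the
    ``synonyms`` alias map (alias -> canonical symbol); duplicates within a
    row collapse to one.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower().replace(".", "_").replace("-", "_") for c in df.columns]
    if "id" not in df.columns or "genes" not in df.columns:
        raise ValueError("pathway table needs at least 'id' and 'genes' columns")
    synonyms = {normalize_symbol(a): normalize_symbol(c) for a, c in (synonyms or {}).items()}

    gene_lists = []
    for pid, cell in zip(df["id"], df["genes"]):
        if pd.isna(cell) or not str(cell).strip():
            warnings.warn(f"pathway {pid} has an empty gene list", stacklevel=2)
            gene_lists.append([])
            continue
        seen: list[str] = []
        for token in str(cell).split("/"):
            token = token.strip()
            if not token:
                continue
            g = normalize_symbol(token)
            g = synonyms.get(g, g)
            if g not in seen:
                seen.append(g)
        gene_lists.append(seen)
    out = df.copy()
    out["genes"] = gene_lists
    return out


def build_tp_network(pathway_table: pd.DataFrame) -> tuple[nx.Graph, dict]:
    """Bipartite pathway-target graph plus its node/edge summary.

    One edge per (pathway, member gene) pair after normalization; the edge
    count equals the sum of per-pathway unique gene counts because targets
    shared between pathways fuse into single nodes.
    """
    g = nx.Graph()
    for row in pathway_table.itertuples(index=False):
        pid = str(row.id).strip()
        name = str(getattr(row, "pathway", pid))
        g.add_node(pid, kind="pathway", name=name)
        for gene in row.genes:
            g.add_node(gene, kind="target")
            g.add_edge(pid, gene)
    pathways = [n for n, k in g.nodes(data="kind") if k == "pathway"]
    targets = [n for n, k in g.nodes(data="kind") if k == "target"]
    stats = {
        "n_pathways": len(pathways),
        "n_targets": len(targets),
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
    }
    return g, stats


def build_ctp_network(ct_net: nx.Graph, tp_net: nx.Graph) -> tuple[nx.Graph, dict]:
    """Merge C-T and T-P layers into the tripartite C-T-P network.

    Target nodes present in both layers fuse into single nodes; a node id
    carrying different ``kind`` attributes in the two layers (e.g. a
    component id colliding with a gene symbol) is an error. The summary
    reports per-kind node counts and per-layer edge counts.
    """
    for node in set(ct_net.nodes) & set(tp_net.nodes):
        k1 = ct_net.nodes[node].get("kind")
        k2 = tp_net.nodes[node].get("kind")
        if k1 != k2:
            raise ValueError(f"node {node!r} is a {k1} in one layer and a {k2} in the other")
    merged = nx.compose(ct_net, tp_net)
    kinds = pd.Series([k for _, k in merged.nodes(data="kind")])
    summary = {
        "n_nodes": merged.number_of_nodes(),
        "n_edges": merged.number_of_edges(),
        "nodes_by_kind": kinds.value_counts().to_dict(),
        "ct_edges": ct_net.number_of_edges(),
        "tp_edges": tp_net.number_of_edges(),
    }
    return merged, summary


def export_network(net: nx.Graph, path, fmt: str) -> None:
    """Write a network as SIF, GraphML or edge TSV.

    GraphML and TSV round-trip node kinds and edge scores; SIF is the bare
    interaction list (one ``u  pp  v`` line per edge, isolated nodes as
    single-token lines).
    """
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(map(lambda e: tuple(sorted(map(str, e))), net.edges())):
                fh.write(f"{u}\tpp\t{v}\n")
            for n in sorted(map(str, nx.isolates(net))):
                fh.write(f"{n}\n")
    elif fmt == "graphml":
        nx.write_graphml(net, path, named_key_ids=True)
    elif fmt == "tsv":
        rows = [
            {
                "source": u,
                "target": v,
                "source_kind": net.nodes[u].get("kind", ""),
                "target_kind": net.nodes[v].get("kind", ""),
                "score": data.get("score", ""),
            }
            for u, v, data in sorted(net.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
        ]
        pd.DataFrame(rows, columns=["source", "target", "source_kind", "target_kind", "score"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def read_network(path, fmt: str) -> nx.Graph:
    """Inverse of :func:`export_network`."""
    fmt = fmt.lower()
    if fmt == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) == 1 and fields[0].strip():
                    g.add_node(fields[0].strip())
                elif len(fields) >= 3:
                    g.add_edge(fields[0].strip(), fields[2].strip())
        return g
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_node(str(row.source), kind=row.source_kind if pd.notna(row.source_kind) else "")
            g.add_node(str(row.target), kind=row.target_kind if pd.notna(row.target_kind) else "")
            attrs = {}
            if "score" in df.columns and pd.notna(row.score) and str(row.score) != "":
                attrs["score"] = float(row.score)
            g.add_edge(str(row.source), str(row.target), **attrs)
        return g
    raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
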