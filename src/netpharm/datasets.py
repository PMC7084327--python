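"""Bundled reference tables for the Hemerocallis Radix / depressive-disorder case study.

The package ships small plain-text transcriptions of the published summary
tables of that analysis: the eleven active-component property rows, the
whitelist of components retained on pharmacological grounds, the reported
cluster summaries of the disease and herb-disease PPI networks, the top-10
enriched KEGG pathways with their member genes, and the gene-alias fixes
needed to make the pathway table's symbols consistent.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .chem_screen import ComponentRecord, read_components
from .ctp_assembly import read_pathway_table

__all__ = [
    "load_hr_components",
    "load_hr_component_table",
    "load_default_whitelist",
    "load_reported_disease_clusters",
    "load_reported_overlap_clusters",
    "load_reported_pathways",
    "load_gene_synonyms",
]

_DATA = files("netpharm") / "data"


def load_hr_component_table() -> pd.DataFrame:
    """Raw component property table (one row per active component)."""
    with (_DATA / "hr_components.csv").open() as fh:
        return pd.read_csv(fh)


def load_hr_components() -> list[ComponentRecord]:
    """Component property rows as validated records."""
    with (_DATA / "hr_components.csv").open() as fh:
        return read_components(fh)


def load_default_whitelist() -> frozenset:
    """Ids of the six components added back after the strict ADME filter."""
    ids = []
    with (_DATA / "hr_whitelist.txt").open() as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return frozenset(ids)


def _load_cluster_table(name: str) -> pd.DataFrame:
    with (_DATA / name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["genes"] = df["genes"].str.split(",")
    return df


def load_reported_disease_clusters() -> pd.DataFrame:
    """Reported cluster summary (score, nodes, edges, members) of the disease PPI network."""
    return _load_cluster_table("dd_clusters.tsv")


def load_reported_overlap_clusters() -> pd.DataFrame:
    """Reported cluster summary of the herb-disease overlap PPI network."""
    return _load_cluster_table("hr_dd_clusters.tsv")


def load_gene_synonyms() -> dict:
    """Alias -> canonical gene symbol fixes for the bundled pathway table."""
    synonyms = {}
    with (_DATA / "gene_synonyms.tsv").open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            alias, canonical = line.split("\t")
            synonyms[alias] = canonical
    return synonyms


def load_reported_pathways(apply_synonyms: bool = True) -> pd.DataFrame:
    """Top-10 enriched KEGG pathways with slash-separated member genes.

    With ``apply_synonyms`` (default) the bundled alias map is applied; the
    published table prints one truncated symbol ("GRIN2") that only
    resolves to a consistent unique-target count as GRIN2B.
    """
    synonyms = load_gene_synonyms() if apply_synonyms else None
    with (_DATA / "kegg_pathways.tsv").open() as fh:
        return read_pathway_table(fh, synonyms=synonyms)
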