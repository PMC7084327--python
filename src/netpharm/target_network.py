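"""Component-target association handling and the bipartite C-T network.

Associations come from one experimentally *identified* source and two
prediction services: ``hitpick`` rows carry a precision score, ``sea`` rows
the maximum Tanimoto similarity (MaxTc) to a known ligand of the target.
Predictions are kept only above their score thresholds (conventionally 0.5
for both); identified associations are kept unconditionally. After the
per-source filter, associations are deduplicated by set union on
(component, target) pairs and summarised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SOURCES",
    "CTStats",
    "normalize_symbol",
    "read_associations",
    "filter_predictions",
    "dedup_union",
    "build_ct_network",
    "ct_stats",
]

SOURCES = ("identified", "hitpick", "sea")

ASSOC_COLUMNS = ["component_id", "target", "source", "score"]


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol; empty symbols are invalid."""
    s = str(symbol).strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    return s


def read_associations(path) -> pd.DataFrame:
    """Read a component->target association table (TSV).

    Columns: ``component_id``, ``target``, ``source`` (identified | hitpick |
    sea) and an optional ``score``. Targets are symbol-normalized on read.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"component_id", "target", "source"} - set(df.columns)
    if missing:
        raise ValueError(f"association table is missing columns: {sorted(missing)}")
    if "score" not in df.columns:
        df["score"] = float("nan")
    df = df[ASSOC_COLUMNS].copy()
    df["target"] = df["target"].map(normalize_symbol)
    df["source"] = df["source"].str.strip().str.lower()
    bad = set(df["source"]) - set(SOURCES)
    if bad:
        raise ValueError(f"unknown association sources: {sorted(bad)}")
    present = df["score"].notna()
    if ((df.loc[present, "score"] < 0) | (df.loc[present, "score"] > 1)).any():
        raise ValueError("association scores must lie in [0, 1]")
    return df


def filter_predictions(
    assocs: pd.DataFrame,
    min_precision: float = 0.5,
    min_maxtc: float = 0.5,
    missing_score: str = "drop",
) -> pd.DataFrame:
    """Keep predicted associations above their source-specific thresholds.

    ``hitpick`` rows are kept iff precision >= ``min_precision``; ``sea``
    rows iff MaxTc >= ``min_maxtc`` (both inclusive); ``identified`` rows
    are always kept. A predicted row with no score is dropped with a warning
    by default (``missing_score``: "drop" | "keep" | "error").
    """
    if missing_score not in {"drop", "keep", "error"}:
        raise ValueError("missing_score must be 'drop', 'keep' or 'error'")
    df = assocs.copy()
    predicted = df["source"].isin(["hitpick", "sea"])
    no_score = predicted & df["score"].isna()
    if no_score.any():
        if missing_score == "error":
            raise ValueError(f"{int(no_score.sum())} predicted rows lack a score")
        if missing_score == "drop":
            warnings.warn(
                f"dropping {int(no_score.sum())} predicted associations without a score",
                stacklevel=2,
            )
            df = df[~no_score]
    df = df.reset_index(drop=True)
    keep = np.ones(len(df), dtype=bool)
    scored = df["score"].notna().to_numpy()
    hp = (df["source"] == "hitpick").to_numpy() & scored
    sea = (df["source"] == "sea").to_numpy() & scored
    keep[hp] = (df.loc[hp, "score"] >= min_precision).to_numpy()
    keep[sea] = (df.loc[sea, "score"] >= min_maxtc).to_numpy()
    return df[keep].reset_index(drop=True)


def dedup_union(assocs: pd.DataFrame) -> tuple[frozenset, frozenset]:
    """Deduplicate associations across sources by set union.

    Returns ``(unique_targets, unique_edges)`` where edges are
    (component_id, target) pairs. Idempotent and independent of row order.
    """
    edges = frozenset(
        (str(c), normalize_symbol(t))
        for c, t in zip(assocs["component_id"], assocs["target"])
    )
    targets = frozenset(t for _, t in edges)
    return targets, edges


def build_ct_network(assocs: pd.DataFrame) -> nx.Graph:
    """Build the bipartite component-target graph from deduplicated edges.

    Component nodes carry ``kind='component'``, targets ``kind='target'``.
    """
    _, edges = dedup_union(assocs)
    g = nx.Graph()
    for c, t in sorted(edges):
        if c == t:
            raise ValueError(f"component id collides with target symbol: {c}")
        g.add_node(c, kind="component")
        g.add_node(t, kind="target")
        g.add_edge(c, t)
    return g


@dataclass(frozen=True)
class CTStats:
    """Summary statistics of a component-target network."""

    n_components: int
    n_targets: int
    n_edges: int
    targets_per_component: float
    mean_component_degree_per_target: float

    def rounded(self, ndigits: int = 1) -> tuple[float, float]:
        """Display form: both ratios rounded (full precision kept on the fields)."""
        return (
            round(self.targets_per_component, ndigits),
            round(self.mean_component_degree_per_target, ndigits),
        )


def ct_stats(n_components: int, n_targets: int, n_edges: int) -> CTStats:
    """Average targets per component and mean component degree per target."""
    if n_components <= 0 or n_targets <= 0:
        raise ValueError("component and target counts must be positive")
    if n_edges < 0:
        raise ValueError("edge count must be non-negative")
    return CTStats(
        n_components=int(n_components),
        n_targets=int(n_targets),
        n_edges=int(n_edges),
        targets_per_component=n_targets / n_components,
        mean_component_degree_per_target=n_edges / n_targets,
    )
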