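"""Hypergeometric over-representation analysis of gene sets.

A query gene list (e.g. the herb/disease overlap targets) is tested against
each set of a GMT collection with the one-sided hypergeometric upper tail
P(X >= k), where k is the observed overlap, K the set size, n the query
size and N the background universe. Raw p-values are corrected with the
Benjamini-Hochberg step-up procedure; the correction supports an explicit
family size ``m_total`` larger than the number of reported sets so that a
printed subset of a bigger test family can be re-adjusted consistently.

The background defaults to the union of all collection genes; pass an
explicit universe when one is known — the choice of universe is the main
driver of absolute p-values in this kind of analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .target_network import normalize_symbol

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_test",
    "bh_adjust",
    "enrich",
]


@dataclass(frozen=True)
class GeneSet:
    """One annotated gene set (pathway, GO category, ...)."""

    set_id: str
    name: str
    genes: frozenset
    category: Optional[str] = None  # e.g. BP / CC / MF; bookkeeping only

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id} is empty")


class GeneSetCollection:
    """A GMT-style collection with a shared background universe.

    Every member gene must lie in the background; when no explicit
    background is given the union of all set members is used.
    """

    def __init__(self, sets: Iterable[GeneSet], background: Optional[Iterable[str]] = None):
        self.sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.set_id in self.sets:
                raise ValueError(f"duplicate set id {s.set_id}")
            self.sets[s.set_id] = s
        union = frozenset().union(*(s.genes for s in self.sets.values())) if self.sets else frozenset()
        if background is None:
            self.background = union
        else:
            self.background = frozenset(normalize_symbol(g) for g in background)
            stray = union - self.background
            if stray:
                raise ValueError(
                    f"{len(stray)} set member genes are outside the explicit background"
                )

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, category: Optional[str] = None) -> list[GeneSet]:
    """Read gene sets from a GMT file (set id, description, tab-separated genes)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs id, description, >=1 gene")
            set_id, name, *genes = fields
            genes = [g for g in genes if g.strip()]
            sets.append(
                GeneSet(
                    set_id=set_id.strip(),
                    name=name.strip(),
                    genes=frozenset(normalize_symbol(g) for g in genes),
                    category=category,
                )
            )
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    """Write gene sets in GMT format (members sorted for reproducible bytes)."""
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.genes)]) + "\n")


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k``: observed overlap, ``K``: annotated set size, ``n``: query size,
    ``N``: background size.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if N < 1 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Sequence[float], m_total: Optional[int] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    adj_i = min_{j >= i} (p_(j) * m_total / j), capped at 1, with results
    returned in the original input order. ``m_total`` defaults to
    ``len(pvals)``; a larger value adjusts a reported subset as part of a
    bigger family of tests.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-d sequence")
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size if m_total is None else int(m_total)
    if m < p.size:
        raise ValueError(f"m_total={m} smaller than the number of p-values ({p.size})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    p_cutoff: float = 0.05,
    top_n: Optional[int] = None,
    m_total: Optional[int] = None,
) -> pd.DataFrame:
    """Over-representation analysis of ``query`` against ``collection``.

    Every set in the collection is tested (the BH family is the whole
    collection, or ``m_total`` when given); results are then screened on the
    raw p-value (``p_raw <= p_cutoff``), sorted ascending by raw p (ties:
    larger overlap, then set id) and truncated to ``top_n`` per category.
    Query genes outside the background are dropped with a warning; an empty
    query after that intersection is an error.
    """
    q = {normalize_symbol(g) for g in query}
    dropped = q - collection.background
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the background were dropped",
            stacklevel=2,
        )
    q &= collection.background
    if not q:
        raise ValueError("query is empty after intersection with the background")
    N = len(collection.background)
    n = len(q)

    rows = []
    for s in collection.sets.values():
        hits = q & s.genes
        rows.append(
            {
                "set_id": s.set_id,
                "name": s.name,
                "category": s.category,
                "k": len(hits),
                "K": len(s.genes),
                "n": n,
                "N": N,
                "p_raw": hypergeom_test(len(hits), len(s.genes), n, N),
                "hit_genes": "/".join(sorted(hits)),
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjust"] = bh_adjust(df["p_raw"].to_numpy(), m_total=m_total)
    df = df[df["p_raw"] <= p_cutoff]
    df = df.sort_values(
        by=["p_raw", "k", "set_id"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)
    if top_n is not None:
        df = (
            df.groupby(df["category"].fillna(""), group_keys=False, sort=False)
            .head(top_n)
            .reset_index(drop=True)
        )
    cols = ["set_id", "name", "category", "k", "K", "n", "N", "p_raw", "p_adjust", "hit_genes"]
    return df[cols]
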