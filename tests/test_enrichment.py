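"""Hypergeometric over-representation, BH adjustment, GMT handling."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm import (
    GeneSet,
    GeneSetCollection,
    bh_adjust,
    enrich,
    hypergeom_test,
    read_gmt,
    write_gmt,
)
from netpharm.synthetic_data import gen_genesets


def enumerate_tail(k, K, n, N):
    """P(overlap >= k) by exhaustive enumeration of all C(N, n) draws."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeomTest:
    def test_degenerate_cases(self):
        assert hypergeom_test(0, 3, 4, 10) == pytest.approx(1.0)
        assert hypergeom_test(5, 10, 5, 10) == pytest.approx(1.0)  # set = background

    def test_hand_enumerated_example(self):
        # 66 of the 252 size-5 draws from a 10-gene universe hit >= 3 of 4
        assert hypergeom_test(3, 4, 5, 10) == pytest.approx(66 / 252)
        assert enumerate_tail(3, 4, 5, 10) == pytest.approx(66 / 252)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_test(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_test(1, 11, 5, 10)

    def test_matches_enumeration_for_all_small_universes(self):
        for N in range(1, 13):
            for n in range(0, N + 1):
                draws = list(itertools.combinations(range(N), n))
                for K in range(0, N + 1):
                    marked = set(range(K))
                    counts = np.bincount(
                        [len(marked.intersection(d)) for d in draws],
                        minlength=min(K, n) + 1,
                    )
                    tail = np.cumsum(counts[::-1])[::-1] / len(draws)
                    for k in range(0, min(K, n) + 1):
                        assert hypergeom_test(k, K, n, N) == pytest.approx(
                            tail[k], rel=1e-9
                        ), (k, K, n, N)


class TestBhAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.04], m_total=1)[0] == pytest.approx(0.04)

    def test_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_family_size_override_validates(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m_total=1)

    def test_matches_statsmodels_without_override(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1, size=40)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p) == pytest.approx(expected)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30))
    def test_monotone_in_sorted_order_and_permutation_invariant(self, pvals):
        adj = bh_adjust(pvals)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
        perm = np.random.default_rng(0).permutation(len(pvals))
        adj_perm = bh_adjust(np.asarray(pvals)[perm])
        assert adj_perm == pytest.approx(adj[perm])
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1.0).all()


class TestEnrich:
    def test_planted_set_ranked_first(self):
        sets, query, planted_id = gen_genesets(
            n_sets=50,
            set_size_range=(20, 40),
            background_size=1000,
            query_size=50,
            planted_overlap=15,
            seed=3,
        )
        collection = GeneSetCollection(sets, background=[f"G{i:05d}" for i in range(1000)])
        results = enrich(query, collection, p_cutoff=0.05)
        assert results.iloc[0]["set_id"] == planted_id
        top = results.iloc[0]
        assert top["k"] == 15
        assert top["p_adjust"] >= top["p_raw"]
        assert len(top["hit_genes"].split("/")) == top["k"]

    def test_disjoint_query_yields_nothing(self):
        sets = [GeneSet("S1", "s", frozenset({"A", "B"}))]
        collection = GeneSetCollection(sets, background=["A", "B", "Q1", "Q2"])
        results = enrich(["Q1", "Q2"], collection, p_cutoff=0.05)
        assert results.empty

    def test_whole_background_set_excluded_at_cutoff(self):
        sets = [GeneSet("S1", "everything", frozenset({"A", "B", "C"}))]
        collection = GeneSetCollection(sets)
        results = enrich(["A", "B"], collection, p_cutoff=0.05)
        assert results.empty  # p = 1 by construction

    def test_query_outside_background_warns_then_errors_when_empty(self):
        sets = [GeneSet("S1", "s", frozenset({"A", "B"}))]
        collection = GeneSetCollection(sets)
        with pytest.warns(UserWarning, match="dropped"):
            enrich(["A", "ZZZ"], collection)
        with pytest.raises(ValueError), pytest.warns(UserWarning, match="dropped"):
            enrich(["ZZZ"], collection)

    def test_per_category_top_n(self):
        rng = np.random.default_rng(8)
        background = [f"G{i}" for i in range(60)]
        query = background[:12]
        sets = []
        for cat in ("BP", "MF"):
            for i in range(4):
                members = set(query[: 6 + i]) | {f"G{50 + i}"}
                sets.append(GeneSet(f"{cat}{i}", f"{cat}-{i}", frozenset(members), category=cat))
        collection = GeneSetCollection(sets, background=background)
        results = enrich(query, collection, p_cutoff=1.0, top_n=2)
        assert (results.groupby("category").size() <= 2).all()


def test_gmt_round_trip(tmp_path):
    sets, _, _ = gen_genesets(5, (5, 10), 50, 10, 3, seed=1)
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path)
    again = read_gmt(path)
    assert {(s.set_id, s.genes) for s in again} == {(s.set_id, s.genes) for s in sets}
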