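"""Target-pathway and component-target-pathway network assembly and export."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netpharm import (
    build_ct_network,
    build_ctp_network,
    build_tp_network,
    export_network,
    read_network,
    read_pathway_table,
)


def pathway_frame(rows):
    df = pd.DataFrame(rows, columns=["id", "pathway", "genes"])
    return df


class TestBuildTpNetwork:
    def test_reported_pathway_table_counts(self, reported_pathways):
        g, stats = build_tp_network(reported_pathways)
        assert stats == {"n_pathways": 10, "n_targets": 23, "n_nodes": 33, "n_edges": 71}
        # edge count equals the sum of per-pathway unique gene counts
        assert stats["n_edges"] == sum(len(genes) for genes in reported_pathways["genes"])

    def test_single_pathway(self):
        g, stats = build_tp_network(pathway_frame([("P1", "p one", ["A", "B"])]))
        assert stats == {"n_pathways": 1, "n_targets": 2, "n_nodes": 3, "n_edges": 2}

    def test_duplicate_gene_in_row_counted_once(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("id\tpathway\tgenes\nP1\tp\tA/B/ a /B\n")
        table = read_pathway_table(path)
        assert table["genes"].iloc[0] == ["A", "B"]

    def test_synonym_normalization(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("id\tpathway\tgenes\nP1\tp\tGRIN2/MAOA\n")
        table = read_pathway_table(path, synonyms={"GRIN2": "GRIN2B"})
        assert table["genes"].iloc[0] == ["GRIN2B", "MAOA"]

    def test_empty_gene_list_warns(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("id\tpathway\tgenes\nP1\tp\t\n")
        with pytest.warns(UserWarning, match="empty gene list"):
            read_pathway_table(path)


class TestBuildCtpNetwork:
    @staticmethod
    def ct_graph(edges):
        df = pd.DataFrame(
            [(c, t, "identified", np.nan) for c, t in edges],
            columns=["component_id", "target", "source", "score"],
        )
        return build_ct_network(df)

    def test_shared_target_fuses(self):
        ct = self.ct_graph([("c1", "T1")])
        tp, _ = build_tp_network(pathway_frame([("P1", "p", ["T1"])]))
        merged, summary = build_ctp_network(ct, tp)
        assert summary["n_nodes"] == 3 and summary["n_edges"] == 2
        assert merged.nodes["T1"]["kind"] == "target"

    def test_disjoint_targets_additive(self):
        ct = self.ct_graph([("c1", "T1")])
        tp, _ = build_tp_network(pathway_frame([("P1", "p", ["T2"])]))
        merged, summary = build_ctp_network(ct, tp)
        assert summary["n_nodes"] == 4
        assert summary["nodes_by_kind"] == {"component": 1, "target": 2, "pathway": 1}

    def test_namespace_collision_rejected(self):
        ct = self.ct_graph([("P1", "T1")])  # component id clashes with pathway id
        tp, _ = build_tp_network(pathway_frame([("P1", "p", ["T1"])]))
        with pytest.raises(ValueError, match="layer"):
            build_ctp_network(ct, tp)

    def test_counts_equal_brute_force_union(self, reported_pathways):
        tp, _ = build_tp_network(reported_pathways)
        targets = sorted(n for n, k in tp.nodes(data="kind") if k == "target")[:10]
        rng = np.random.default_rng(6)
        edges = [
            (f"c{rng.integers(3)}", t) for t in targets for _ in range(rng.integers(1, 3))
        ]
        ct = self.ct_graph(edges)
        merged, summary = build_ctp_network(ct, tp)
        expected_nodes = set(ct.nodes) | set(tp.nodes)
        expected_edges = {frozenset(e) for e in ct.edges} | {
            frozenset(e) for e in tp.edges
        }
        assert set(merged.nodes) == expected_nodes
        assert {frozenset(e) for e in merged.edges} == expected_edges
        n_components = sum(1 for _, k in merged.nodes(data="kind") if k == "component")
        n_pathways = sum(1 for _, k in merged.nodes(data="kind") if k == "pathway")
        n_targets = sum(1 for _, k in merged.nodes(data="kind") if k == "target")
        assert summary["n_nodes"] == n_components + n_pathways + n_targets


class TestExport:
    def test_sif_triangle(self, tmp_path):
        g = nx.complete_graph(["A", "B", "C"])
        path = tmp_path / "net.sif"
        export_network(g, path, "sif")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3 and all("\tpp\t" in line for line in lines)
        again = read_network(path, "sif")
        assert nx.utils.graphs_equal(nx.Graph(again.edges), nx.Graph(g.edges))

    @pytest.mark.parametrize("fmt", ["graphml", "tsv"])
    def test_typed_round_trip(self, fmt, tmp_path):
        g = nx.Graph()
        g.add_node("c1", kind="component")
        g.add_node("T1", kind="target")
        g.add_node("P1", kind="pathway")
        g.add_edge("c1", "T1")
        g.add_edge("T1", "P1")
        path = tmp_path / f"net.{fmt}"
        export_network(g, path, fmt)
        again = read_network(path, fmt)
        assert set(again.nodes) == set(g.nodes)
        assert {frozenset(e) for e in again.edges} == {frozenset(e) for e in g.edges}
        assert all(again.nodes[n]["kind"] == g.nodes[n]["kind"] for n in g.nodes)

    def test_random_graph_round_trip_by_ids(self, tmp_path):
        g = nx.gnp_random_graph(100, 0.05, seed=12)
        g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})
        nx.set_node_attributes(g, "protein", "kind")
        path = tmp_path / "net.graphml"
        export_network(g, path, "graphml")
        again = read_network(path, "graphml")
        assert set(again.nodes) == set(g.nodes)
        assert {frozenset(e) for e in again.edges} == {frozenset(e) for e in g.edges}

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(nx.Graph(), tmp_path / "x", "gexf")
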