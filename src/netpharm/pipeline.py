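"""End-to-end pipeline orchestration.

Chains the six analysis stages — ADME screen, component-target network,
PPI filtering + target intersection, cluster detection, over-representation
analysis, and component-target-pathway assembly — from a single config
mapping, writing a deterministic directory layout plus a run manifest with
input checksums and all effective parameters.

Any input not supplied in the config is replaced by a bundled fixture
(component table, whitelist) or a synthetic stand-in generated from the run
seed, so a bare ``run_pipeline({}, out, seed=1)`` exercises every stage
offline.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from . import datasets
from .chem_screen import ScreenThresholds, adme_screen, read_components
from .ctp_assembly import build_ctp_network, build_tp_network, export_network
from .enrichment import GeneSet, GeneSetCollection, enrich, read_gmt
from .mcode import McodeParams, clusters_to_frame, find_clusters
from .ppi_tools import degree_ranking, intersect_subnetwork, load_ppi
from .synthetic_data import gen_associations, gen_planted_graph, planted_graph_to_edge_table
from .target_network import build_ct_network, ct_stats, dedup_union, filter_predictions, read_associations

__all__ = ["DEFAULT_PARAMS", "run_pipeline"]

DEFAULT_PARAMS = {
    "min_ob": 30.0,
    "min_caco2": -0.4,
    "min_dl": 0.18,
    "gi_class": "High",
    "max_lipinski_violations": 1,
    "min_precision": 0.5,
    "min_maxtc": 0.5,
    "ppi_confidence": 0.7,
    "k_core_disease": 5,
    "k_core_overlap": 2,
    "p_cutoff": 0.05,
    "top_n": 10,
    "hub_k": 10,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _synthetic_world(seed: int) -> dict:
    """Deterministic stand-in inputs sharing one gene universe."""
    rng = np.random.default_rng(seed)
    universe = [f"G{i:04d}" for i in range(300)]
    disease = universe[60:260]
    # sparse interactions among disease genes, plus two dense planted modules
    g, truth = gen_planted_graph(0, 0.0, [8, 8], seed=seed)
    mapping = {}
    clique_nodes = sorted(g.nodes)
    picked = rng.choice(disease, size=len(clique_nodes), replace=False)
    for old, new in zip(clique_nodes, picked):
        mapping[old] = str(new)
    g = nx.relabel_nodes(g, mapping)
    rest = sorted(set(disease) - set(g.nodes))
    for i in range(len(rest)):
        for j in range(i + 1, len(rest)):
            if rng.random() < 0.015:
                g.add_edge(rest[i], rest[j])
    edges = planted_graph_to_edge_table(g, score=990)
    # thin the background scores so the confidence filter has work to do
    scores = rng.integers(400, 1001, size=len(edges))
    clique_edge = edges.apply(
        lambda r: any(r["node1"] in truthset and r["node2"] in truthset for truthset in
                      [set(mapping[m] for m in members) for members in truth.values()]),
        axis=1,
    )
    edges["combined_score"] = np.where(clique_edge, 950, scores)
    return {"universe": universe, "disease_targets": disease, "ppi_edges": edges}


def run_pipeline(config: Optional[dict], out_dir, seed: int = 0) -> dict:
    """Run the full analysis and return the manifest (also written to disk).

    ``config`` keys (all optional): ``components``, ``whitelist``,
    ``associations``, ``ppi_edges``, ``disease_targets``, ``gmt``, and any
    of the parameter names in :data:`DEFAULT_PARAMS`.
    """
    config = dict(config or {})
    params = {**DEFAULT_PARAMS, **{k: config[k] for k in DEFAULT_PARAMS if k in config}}
    out = Path(out_dir)
    for sub in ("report", "networks", "clusters", "enrichment"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    inputs: dict[str, dict] = {}
    stages: list[dict] = []

    def register_input(name: str, path) -> None:
        inputs[name] = {"path": str(path), "sha256": _sha256(path)} if path else {"path": None}

    # --- stage 1: ADME screen -------------------------------------------------
    if "components" in config:
        records = read_components(config["components"])
        register_input("components", config["components"])
    else:
        records = datasets.load_hr_components()
        register_input("components", None)
    if "whitelist" in config:
        whitelist = frozenset(
            line.strip()
            for line in Path(config["whitelist"]).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        )
        register_input("whitelist", config["whitelist"])
    else:
        whitelist = datasets.load_default_whitelist()
        register_input("whitelist", None)
    thresholds = ScreenThresholds(
        min_ob=params["min_ob"],
        min_caco2=params["min_caco2"],
        min_dl=params["min_dl"],
        gi_class=params["gi_class"],
        max_lipinski_violations=params["max_lipinski_violations"],
    )
    report = adme_screen(records, thresholds, whitelist)
    report.table.to_csv(out / "report" / "screen_report.csv")
    (out / "report" / "screen_summary.json").write_text(
        json.dumps(report.summary(), indent=2, sort_keys=True) + "\n"
    )
    retained = sorted(report.retained_ids)
    stages.append({"name": "screen", "outputs": ["report/screen_report.csv", "report/screen_summary.json"]})

    # --- stage 2: component-target network -----------------------------------
    world = None
    if "associations" in config:
        assocs = read_associations(config["associations"])
        register_input("associations", config["associations"])
    else:
        world = _synthetic_world(seed)
        assocs = gen_associations(retained, world["universe"][:150], seed=seed)
        register_input("associations", None)
    assocs = filter_predictions(assocs, params["min_precision"], params["min_maxtc"])
    targets, edges = dedup_union(assocs)
    ct_net = build_ct_network(assocs)
    stats = ct_stats(len(retained), len(targets), len(edges))
    pd.DataFrame(sorted(edges), columns=["component_id", "target"]).to_csv(
        out / "networks" / "ct_edges.tsv", sep="\t", index=False
    )
    (out / "networks" / "ct_stats.json").write_text(
        json.dumps(
            {
                "n_components": stats.n_components,
                "n_targets": stats.n_targets,
                "n_edges": stats.n_edges,
                "targets_per_component": round(stats.targets_per_component, 3),
                "mean_component_degree_per_target": round(
                    stats.mean_component_degree_per_target, 3
                ),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    stages.append({"name": "ct_network", "outputs": ["networks/ct_edges.tsv", "networks/ct_stats.json"]})

    # --- stage 3: PPI filter + herb/disease intersection ---------------------
    if "ppi_edges" in config:
        ppi = load_ppi(config["ppi_edges"], params["ppi_confidence"])
        register_input("ppi_edges", config["ppi_edges"])
    else:
        world = world or _synthetic_world(seed)
        ppi = load_ppi(world["ppi_edges"], params["ppi_confidence"])
        register_input("ppi_edges", None)
    if "disease_targets" in config:
        disease = [
            line.strip()
            for line in Path(config["disease_targets"]).read_text().splitlines()
            if line.strip()
        ]
        register_input("disease_targets", config["disease_targets"])
    else:
        world = world or _synthetic_world(seed)
        disease = world["disease_targets"]
        register_input("disease_targets", None)
    export_network(ppi, out / "networks" / "ppi_filtered.tsv", "tsv")
    overlap_net, venn = intersect_subnetwork(targets, disease, ppi)
    export_network(overlap_net, out / "networks" / "overlap_ppi.tsv", "tsv")
    hubs = degree_ranking(ppi, params["hub_k"]) if ppi.number_of_nodes() else []
    (out / "networks" / "ppi_summary.json").write_text(
        json.dumps(
            {
                "ppi_nodes": ppi.number_of_nodes(),
                "ppi_edges": ppi.number_of_edges(),
                "venn": venn,
                "top_hubs": hubs,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    stages.append(
        {
            "name": "ppi_intersect",
            "outputs": [
                "networks/ppi_filtered.tsv",
                "networks/overlap_ppi.tsv",
                "networks/ppi_summary.json",
            ],
        }
    )

    # --- stage 4: cluster detection ------------------------------------------
    disease_clusters = find_clusters(ppi, McodeParams(k_core=params["k_core_disease"]))
    overlap_clusters = find_clusters(overlap_net, McodeParams(k_core=params["k_core_overlap"]))
    clusters_to_frame(disease_clusters).to_csv(
        out / "clusters" / "disease_clusters.tsv", sep="\t", index=False
    )
    clusters_to_frame(overlap_clusters).to_csv(
        out / "clusters" / "overlap_clusters.tsv", sep="\t", index=False
    )
    stages.append(
        {"name": "clustering", "outputs": ["clusters/disease_clusters.tsv", "clusters/overlap_clusters.tsv"]}
    )

    # --- stage 5: over-representation analysis -------------------------------
    overlap_genes = sorted(overlap_net.nodes) or sorted(targets)
    if "gmt" in config:
        collection = GeneSetCollection(read_gmt(config["gmt"]))
        register_input("gmt", config["gmt"])
    else:
        world = world or _synthetic_world(seed)
        rng = np.random.default_rng(seed + 1)
        background = sorted(set(world["universe"]) | set(overlap_genes))
        planted = overlap_genes[: min(10, len(overlap_genes))]
        fill = rng.choice(
            sorted(set(background) - set(planted)), size=max(0, 20 - len(planted)), replace=False
        )
        sets = [GeneSet("SET000", "planted", frozenset(list(planted) + list(fill)))]
        for i in range(1, 30):
            members = rng.choice(background, size=int(rng.integers(15, 40)), replace=False)
            sets.append(GeneSet(f"SET{i:03d}", f"decoy-{i}", frozenset(members)))
        collection = GeneSetCollection(sets, background=background)
        register_input("gmt", None)
    results = enrich(
        overlap_genes, collection, p_cutoff=params["p_cutoff"], top_n=params["top_n"]
    )
    results.to_csv(out / "enrichment" / "results.tsv", sep="\t", index=False)
    stages.append({"name": "enrichment", "outputs": ["enrichment/results.tsv"]})

    # --- stage 6: component-target-pathway assembly --------------------------
    pathway_table = results.rename(columns={"set_id": "id", "name": "pathway"})[
        ["id", "pathway", "hit_genes"]
    ].copy()
    pathway_table["genes"] = pathway_table["hit_genes"].map(
        lambda cell: [g for g in str(cell).split("/") if g]
    )
    tp_net, tp_stats = build_tp_network(pathway_table)
    ctp_net, ctp_summary = build_ctp_network(ct_net, tp_net)
    export_network(ctp_net, out / "networks" / "ctp.graphml", "graphml")
    (out / "networks" / "ctp_summary.json").write_text(
        json.dumps({"tp": tp_stats, "ctp": ctp_summary}, indent=2, sort_keys=True) + "\n"
    )
    stages.append({"name": "ctp_assembly", "outputs": ["networks/ctp.graphml", "networks/ctp_summary.json"]})

    manifest = {
        "package": "netpharm",
        "version": __version__,
        "seed": int(seed),
        "parameters": params,
        "inputs": inputs,
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
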