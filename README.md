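# netpharm

An offline network-pharmacology toolkit for tracing how the constituents of
a medicinal herb may act on a disease. It implements the standard
herb-to-mechanism workflow end to end:

1. **ADME screening** of candidate components — oral bioavailability
   (OB ≥ 30 %), Caco-2 permeability (> −0.4), Tanimoto drug-likeness
   (DL ≥ 0.18), gastrointestinal absorption class (High), and Lipinski's
   rule of five (≤ 1 violation), with a whitelist add-back for components
   retained on pharmacological grounds.
2. **Component–target (C-T) network** construction from identified and
   predicted associations (HitPick-style precision ≥ 0.5, SEA-style
   MaxTc ≥ 0.5), with cross-source deduplication and degree statistics.
3. **PPI filtering and target intersection** — STRING-dialect edge tables
   filtered at a combined-score confidence cutoff (0.7), hub ranking, and
   induction of the herb∩disease overlap subnetwork.
4. **MCODE-style cluster detection** — k-core vertex weighting, seeded
   greedy growth, haircut/fluff post-processing, a K-core admission filter,
   and the cluster score *density × size* = 2E/(N−1).
5. **Over-representation analysis** — exact hypergeometric upper-tail tests
   of a query gene list against GMT gene-set collections, with
   Benjamini–Hochberg FDR adjustment supporting an explicit family size.
6. **Component–target–pathway (C-T-P) assembly** — bipartite
   target–pathway and tripartite union networks, exported as SIF, GraphML
   or edge TSV.

Every stage that would normally require a live database query (TCMSP,
PubChem, STRING, DisGeNET, KEGG, …) is instead served by bundled reference
tables or by the `synthetic_data` generators, which produce inputs with
known ground truth (pass/fail screening labels, planted cliques, planted
enriched gene sets) so the whole pipeline is testable with no network
access.

The package ships transcriptions of the summary tables from a published
case study of *Hemerocallis* Radix (daylily root, a Traditional Chinese
Medicine) against depressive disorder, and the test suite reproduces that
study's desk-scale numbers from them.

## Worked example

```python
>>> from netpharm import adme_screen, cluster_score, ct_stats, build_tp_network
>>> from netpharm import datasets

>>> report = adme_screen(datasets.load_hr_components(),
...                      whitelist=datasets.load_default_whitelist())
>>> sorted(report.strict_ids)
['HR01', 'HR06', 'HR07', 'HR08', 'HR10']
>>> len(report.retained_ids)
11
```

Five of the eleven components (aloe-emodin, colchicine, hemerocallone,
kaempferol, rhein) pass all five strict criteria; the whitelist restores
the other six, giving the 11 active components used downstream.

```python
>>> ct_stats(11, 267, 509).rounded(1)
(24.3, 1.9)
```

With 509 associations between 11 components and 267 targets, each
component hits 24.3 targets on average and each target is hit by 1.9
components — the multi-component, multi-target signature.

```python
>>> cluster_score(63, 1042)   # densest disease-network cluster
33.61290322580645
>>> _, stats = build_tp_network(datasets.load_reported_pathways())
>>> stats
{'n_pathways': 10, 'n_targets': 23, 'n_nodes': 33, 'n_edges': 71}
```

The cluster score is internal density × node count; the target–pathway
network links the top-10 enriched KEGG pathways to their 23 unique member
targets through 71 edges.

## Command line

```sh
netpharm screen --components table.csv --whitelist ids.txt --out report/
netpharm ppi --edges string.tsv --cutoff 0.7
netpharm mcode --edges net.tsv --k-core 5
netpharm enrich --query genes.txt --gmt sets.gmt --cutoff 0.05 --top 10
netpharm simulate graph --seed 1 --out sim/
netpharm run --config run.yaml --out results/ --seed 1
```

`netpharm run` chains all six stages from a YAML/JSON config (any missing
input falls back to a bundled fixture or a seeded synthetic stand-in) and
writes a deterministic directory layout plus `manifest.json` with input
checksums and all effective parameters.

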