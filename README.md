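# ixnet

An interaction-network toolkit for systems-biology workflows:

- **Interaction store** — loads custom TSV and minimal PSI-MI TAB 2.5
  interaction tables for proteins, metabolites and drugs, collapses
  duplicate evidence under canonical `id1_id2_pmid` pair keys, and
  indexes pairs, publications and annotations for fast lookup
  (`ixnet.store`).
- **Confidence scoring** — an additive class score over evidence type,
  publication record and co-localization (classes A–E with rendering
  widths 2.5–0.5), a neighborhood-overlap FSW weight with pseudo-count
  correction, and batch-standardized binomial-proportion node p-values
  (`ixnet.scoring`).
- **Network building** — breadth-first seed expansion to first/second/
  third neighbors with induced-subgraph edge semantics, optional bait
  attachment for two-hybrid style experiments, an ordered filter
  pipeline (class score → p-value → degree-0/1 deletion → FSW), and
  fold-change expression annotation with closed cutoff boundaries
  (`ixnet.builder`).
- **Term enrichment** — upper-tail hypergeometric enrichment of GO-BP /
  KEGG style term catalogs against a background organism; exact integer
  combinatorics for terms up to 1,800 background members, log-gamma
  summation beyond; per-node best-term cluster assignment
  (`ixnet.enrichment`).
- **Topology diagnostics** — degree / FSW distributions, power-law slope
  by log-log least squares, average degree, and class composition of the
  top-ranked FSW edges (`ixnet.topology`).
- **XGMML I/O** — deterministic, Cytoscape-2.8-compatible XGMML export
  with typed node/edge attributes ("Selected CC", "Top Enriched BP",
  "FSW", …) and a reader for round-tripping (`ixnet.xgmml`).
- **Synthetic fixtures** — seeded generators for stores, catalogs,
  publication tables, seed lists and fold-change tables with
  controllable scale-free topology and evidence composition
  (`ixnet.fixtures`), so the whole test suite runs offline.

## CLI

```sh
# generate a complete synthetic store directory + query files
ixnet synth --seed 7 --n-seeds 5 --out demo/

# expand seeds into a scored, filtered, annotated XGMML network
ixnet build-network --seeds demo/seeds.txt --store demo \
    --depth 2 --class-cutoff C --prune-degree01 \
    --fc demo/foldchange.txt --fc-up 1.3 --fc-down -1.3 \
    --background-organism synthia -o demo/net.xgmml

# enrichment report and topology summary for a saved network
ixnet enrich --network demo/net.xgmml --terms demo/bp.gmt \
    --store demo --background synthia -o demo/enrichment.tsv
ixnet topology --network demo/net.xgmml -o demo/topology.tsv
```

`ixnet synth --spec spec.yaml` accepts a YAML file whose keys are
`SyntheticStoreSpec` fields (`n_proteins`, `attachment_m`,
`evidence_fsw_coupling`, `rng_seed`, …).

## Store directory layout

| file | format |
| --- | --- |
| `interactions.tsv` | `id_a  id_b  organism_a  organism_b  evidence  method  pmid  source_db` (`.` = missing) |
| `publications.tsv` | `pmid  interaction_count` |
| `cc.gmt`, `bp.gmt`, `kegg.gmt` | GMT-like: `term_id  term_name  id1  id2 …` |
| `symbols.tsv` | `symbol  id  reviewed(0/1)  organism` |
| `orthologs.tsv` | `source_id  source_organism  target_id  target_organism` |
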