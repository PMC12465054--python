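# dmcompare

Cross-disease-map comparison toolkit. Given two annotated molecular-interaction
disease maps, `dmcompare` computes:

- **shared / disease-specific identifiers** (HGNC symbols by default, with
  ChEBI ids for small molecules and normalized names for phenotypes),
- **per-diagram identifier overlap matrices** and a ranked symbol-by-diagram
  incidence table,
- **cell-type similarity** via the Jaccard index over per-compartment protein
  profiles,
- **cross-map interaction matches** (participant-set Jaccard ≥ 0.7 with at
  least two matching elements by default),
- **similarity groups**: pairs of strongly connected components of the two
  reaction graphs linked by at least five matched interactions, plus coverage
  statistics, per-identifier group frequencies and disease-specific clusters,
- **drug-target projections** onto the similarity groups from DrugBank/
  ChEMBL-style TSV tables, and
- **MINERVA-dialect data overlays** from variant gene lists and differential
  expression tables (log fold changes max-abs scaled to [-1, 1]).

A synthetic map-pair generator with a ground-truth manifest makes every
pipeline stage testable without network access.

## Map formats

Maps are read either from the **native JSON format** (`"format":
"dmcompare-map"`, version 1) that mirrors the in-memory model — diagrams,
elements with `(namespace, value)` annotation pairs, signed interactions with
source/target/modifier roles — or from a **MINERVA project export** (JSON with
per-model `elements`/`reactions`); the field-by-field mapping is documented on
the adapter in `src/dmcompare/model.py`.

## CLI

```bash
# generate a synthetic pair with ground truth
dmcompare simulate --seed 1 -o sim/

# full comparison pipeline (all stage TSVs + report.json into out/)
dmcompare compare sim/map_a.json sim/map_b.json -o out/ \
    --drug-table sim/drug_targets.tsv

# MINERVA exports instead of native files
dmcompare compare uc_export.json ad_export.json -o out/ --minerva

# individual stages
dmcompare jaccard sim/map_a.json sim/map_b.json
dmcompare overlay lfc.tsv --mode EXPRESSION -o overlay.tsv
dmcompare drugs out/groups.json sim/drug_targets.tsv

# download a MINERVA project export (the only networked command)
dmcompare fetch "UCmaps31-01–25" \
    --base-url https://imi-immuniverse.elixir-luxembourg.org/minerva \
    -o data/uc_export.json
```

Thresholds live in a `ComparisonConfig` (JSON/YAML config file via
`--config`, overridable by flags); the effective configuration is echoed into
`report.json`. Exit codes: 0 success, 1 usage error, 2 data error.

## Layout

| module | contents |
| --- | --- |
| `dmcompare.model` | data model, native JSON format, MINERVA adapter, canonicalization |
| `dmcompare.identifiers` | unique/shared identifier sets, diagram overlaps, cell-type Jaccard |
| `dmcompare.matching` | participant sets, interaction similarity, match filtering |
| `dmcompare.grouping` | reaction graphs, SCCs, similarity groups, coverage, specific clusters |
| `dmcompare.overlays` | variant/expression overlays, max-abs scaling, overlay TSV dialect |
| `dmcompare.drugs` | drug-target table loading and per-group drug reports |
| `dmcompare.simulate` | synthetic map-pair generator + truth manifest + recovery scoring |
| `dmcompare.pipeline` / `dmcompare.cli` | orchestration, combined report, command line |
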