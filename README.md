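# biomlite

A Python implementation of the **BIOM (Biological Observation Matrix) v1.0.0
file format** for sample-by-observation contingency tables — the core data
type shared by marker-gene surveys (OTU tables), metagenomics (gene/taxon
tables), comparative genomics, and metabolomics — together with the table
operations and analyses that motivate the format.

It is aimed at people who move abundance tables between pipelines (QIIME-style
OTU tables, spreadsheet exports) and want a single, validated, metadata-carrying
representation, plus the standard downstream primitives: filtering, taxonomic
collapsing, rarefaction, and richness estimation.

## What it provides

* **Core model** — `Table`: observations (rows) × samples (columns) with
  per-axis metadata, backed interchangeably by a *sparse* coordinate list
  (`[row, column, value]` triples, zeros implicit) or a *dense* grid. The
  fraction of non-zero cells is the table's **density**.
* **BIOM v1.0.0 JSON I/O** — `parse_biom` / `write_biom` with a canonical,
  compact, byte-deterministic rendering, and `validate`, which turns any input
  into a structured `ValidationReport` instead of raising.
* **Classic OTU table I/O** — lossless conversion to/from the legacy
  tab-separated format (`#OTU ID` header, optional trailing
  `Consensus Lineage` taxonomy column).
* **Table operations** — `filter_samples` / `filter_observations` and
  `collapse_observations` (merge OTUs sharing a truncated taxonomy lineage,
  summing counts; totals conserved).
* **Diversity statistics** — `rarefy` (without-replacement, multivariate
  hypergeometric subsampling to fixed depth), `rarefaction_curve`, and the
  **Chao1** richness estimator

  S₁ = S_obs + F₁²/(2F₂)  (classic; bias-corrected form
  S_obs + F₁(F₁−1)/(2(F₂+1)) when F₂ = 0 or on request),

  where F₁/F₂ are singleton/doubleton counts.
* **File-size benchmarks** — a seeded synthetic-table generator
  (`SynthSpec`/`generate_table`), byte-size reports per serialization,
  density sweeps, the dense/sparse crossover search, and a log-log power-law
  fit `ratio = a · density^b` of the **compression ratio** (classic TSV bytes
  ÷ sparse BIOM bytes).
* **CLI** — `biomlite convert | validate | summarize | benchmark`.

## Worked example

```python
from biomlite import (SynthSpec, generate_table, density, size_report,
                      as_array, chao1, rarefaction_curve)

table = generate_table(SynthSpec(n_samples=200, n_observations=300,
                                 density=0.05, seed=11))
print(table.shape, density(table))          # (300, 200) 0.05
r = size_report(table)
print(r.sparse_biom_bytes, r.dense_biom_bytes, r.classic_tsv_bytes)
print(round(r.compression_ratio, 2))

col = as_array(table)[:, 0]                 # counts in sample S0
print((col > 0).sum(), (col == 1).sum(), (col == 2).sum())
print(round(chao1(col.tolist()), 1))

curve = rarefaction_curve(table, depths=[1, 5, 10, 20], reps=50, seed=0)
print([round(m, 2) for m in curve.mean_richness])
```

prints

```
(300, 200) 0.05
78687 166073 147290
1.87
15 7 5
19.9
[1.0, 4.42, 7.68, 12.35]
```

Reading the numbers: at 5% density the sparse BIOM file (78,687 B) is about
half the dense BIOM file and 1.87× smaller than the classic TSV. Sample `S0`
holds 15 observed OTUs with 7 singletons and 5 doubletons, so Chao1
extrapolates 15 + 7²/(2·5) ≈ 19.9 OTUs. The collector curve rises from
exactly 1 observation at depth 1 toward the per-sample richness as
subsampling depth grows.

The same sweep from the shell:

```
$ biomlite benchmark --shape 300 300 --densities "0.05,0.10,0.20,0.40" --seed 1 --crossover
density	sparse_biom_bytes	dense_biom_bytes	classic_tsv_bytes	compression_ratio
0.05	99171	229065	207783	2.0952
0.1	149880	229047	207765	1.38621
0.2	251456	229088	207806	0.826411
0.4	454122	229161	207879	0.45776
crossover	0.2
```

The compression ratio falls as density rises, and for this 300×300 table the
dense rendering overtakes the sparse one at 20% density (the crossover sits
near 15–17% for 1000×1000 tables, whose larger row/column indices make each
sparse triple more expensive).

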