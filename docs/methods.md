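# Methods

## The data model

A contingency table records abundances of *observations* (OTUs, genes,
pathways, metabolites) per *sample*. biomlite fixes the orientation once:
rows are observations, columns are samples, indices are 0-based. Two
interchangeable backings exist:

* **sparse** — a coordinate list of `(row, column, value)` triples, stored
  and serialized sorted row-major; zeros are implicit. Explicit zeros handed
  to a constructor are dropped silently; duplicate coordinates are a
  construction error (at the *file* level the validator reports them, it
  never throws).
* **dense** — a full row-major grid.

Every operation is defined to return identical results on either backing;
the test suite asserts this duality directly. `element_type` is `int`,
`float`, or `unicode`; unicode tables support structural operations
(conversion, filtering, validation) but reject arithmetic. For unicode
tables the implicit "zero" of an absent sparse cell is the empty string.

**Density** is the fraction of cells with a non-zero value. It is undefined
(an error) when either axis is empty, because the cell count is zero.

## BIOM v1.0.0 serialization

A document is one JSON object with twelve required keys, written in this
order: `id, format, format_url, type, generated_by, date, rows, columns,
matrix_type, matrix_element_type, shape, data`. The writer emits a canonical
compact form: no insignificant whitespace, integers without a decimal point,
floats in their shortest round-trip decimal representation (Python's `repr`,
i.e. the `json` module's default). File sizes are therefore well defined,
which the benchmark module depends on; all byte counts in this package are
UTF-8 byte lengths of that canonical form. The parser accepts any key order
and whitespace, and preserves unknown top-level keys on a provenance map
(`Table.extra`) that the writer never re-emits.

Validator policy — errors are violations that prevent loading the document
into a table (missing required keys, shape/axis mismatches, out-of-range or
duplicate sparse coordinates, malformed dense rows, duplicate axis ids, bad
`matrix_type`/`matrix_element_type`); everything else warns (explicit zeros
in sparse data, non-ISO-8601 dates, unexpected `format`/`format_url` values,
unconventional `type` strings). `type` only warns because the format does
not change across data types; tolerating dialect drift in the format strings
keeps the validator useful on files written by other tools.

## Classic OTU tables

The legacy tab-separated format has a `#OTU ID` header and at most one
metadata column, the trailing `Consensus Lineage`. Conversion is therefore
inherently lossy for any other metadata: non-taxonomy observation metadata
and all sample metadata are dropped with a logged warning. The lineage is
joined with `"; "` on write and split on `";"` (whitespace stripped) on
parse, so bare-semicolon files are accepted. Counts parse as `int` when
every value is integral — including `1.0`-style floats that older tools
wrote — and `float` otherwise; the writer renders integer tables without
decimal points. Duplicate OTU ids are a parse error.

## Filtering and collapsing

Filters receive `(id, metadata, axis total)` per entry, preserve relative
order, and never mutate the input. A filter may legally empty one axis (a
`0 × k` table is valid); emptying both is an error. Collapsing groups
observations by the first `level` elements of a list-valued metadata entry
(a bare string counts as a 1-element lineage), sums their rows, and names
each merged observation by the `"; "`-joined truncated lineage in
first-appearance order. Under the strict missing-metadata policy (default)
the grand total and every per-sample total are conserved; the `drop` policy
instead excludes offending observations and logs how many were dropped.

## Rarefaction and Chao1

Rarefaction subsamples each sample *without replacement* to exactly `depth`
counts — a multivariate hypergeometric draw — matching collector-curve
semantics (a with-replacement multinomial would overweight abundant
observations at small depths). Samples with totals below the depth are
dropped; the observation axis is untouched. Randomness derives from one
master seed, but each `(sample id, depth, replicate)` gets its own
deterministic stream (seeded via CRC-32 of the sample id), so results do not
depend on sample order or on which other depths are evaluated.

A rarefaction curve reports, per depth, the *mean per-sample richness* —
the number of observations with non-zero count in a sample, averaged over
retained samples and replicates. Per-sample aggregation is the conventional
collector-curve reading and gives the two boundary identities the tests pin
down: depth 1 yields exactly 1.0, and depth equal to a sample's total
reproduces its observed richness. The mean (not median) over replicates is
used. In expectation the curve is non-decreasing in depth; the property test
allows one unit of slack on 100-replicate means.

Chao1 uses the classic form S_obs + F₁²/(2F₂) and switches to the
bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)) when F₂ = 0 (avoiding the
division by zero) or when `bias_corrected=True`. Counts must be non-negative
integers; the estimate never falls below observed richness.

## Synthetic tables and the size benchmarks

`generate_table` places exactly `round(density × cells)` non-zero cells
uniformly at random without collision and draws values from one of three
distributions — `unit` (all ones), `geometric(p)` (default, p = 0.5: counts
heavy in 1s and 2s, the shape of real OTU tables), or `uniform_int(lo, hi)`
with lo ≥ 1 so no value is zero. `taxonomy_depth` (default 7,
kingdom→species) attaches a fixed-vocabulary lineage to every observation,
emulating the single taxonomy metadata entry real OTU tables carry. A
density-1.0 request returns a dense backing; everything else is sparse.
Generation is fully deterministic given the seed; generated tables carry a
fixed creation date so serialization is byte-reproducible.

The **compression ratio** is classic-TSV bytes divided by sparse-BIOM bytes,
both under the canonical compact writers. Absolute megabyte figures are not
meaningful without fixing a rendering, so this package defines one and
targets only ratios and crossovers. At 1% density a table stores 100-fold
fewer counts in sparse form but the file is only ~10-fold smaller, because
each triple spells out its row and column; as density grows that positional
overhead dominates and the dense rendering wins — at ~17% for 1000×1000
geometric-count tables (each index averages ~2.9 digits there; smaller
tables cross slightly higher, and the crossover is insensitive to metadata,
which both renderings share).

`find_dense_sparse_crossover` is a linear sweep (default 1-percentage-point
steps), not a bisection, because byte sizes can jitter at small shapes; it
returns the smallest swept density where dense ≤ sparse, or `None`.
`fit_power_law` fits `log ratio` on `log density` by least squares and
reports R² on the log scale — the scale on which the model is linear; a
constant-ratio input has zero residual around the flat fit and reports
R² = 1.

## Problem sizes used in the checks

The end-to-end checks generate a 6,164-sample × 7,082-observation table at
1% density (≈436k non-zero cells, ≈88 MB of TSV) for the 10-fold size
relation, and sweep 1000×1000 tables over densities 1%–50% for the
crossover; the statistical checks use 10,000 replicate subsampling draws
against exact hypergeometric probabilities (3-standard-error bands) and
exhaustive enumeration of small count vectors for Chao1.

## Known limitations and non-goals

* What the generator does **not** emulate: correlated sample compositions,
  rank-abundance (log-series) tails, taxonomically clustered co-occurrence,
  or rich free-text metadata. Passing size benchmarks on synthetic tables
  therefore demonstrates the *density dependence* of the serializations, not
  the absolute sizes of any particular real survey, which depend on id
  lengths and metadata payloads.
* BIOM 2.x (HDF5) is out of scope, as are streaming parsers for multi-GB
  files: documents are materialized in memory.
* Metadata is carried opaquely; no schema (MIxS/ISA-TAB) checking.
* Sample-axis collapsing and relative-abundance transforms are not
  provided.
* Chao1 confidence intervals are not computed.
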