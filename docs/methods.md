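# Methods

## Classification model

Annotation assigns each input row a matrisome *division* and *category*
from a fixed two-level taxonomy. The six categories map onto the two
divisions deterministically:

| Category | Division |
|---|---|
| ECM Glycoproteins | Core matrisome |
| Collagens | Core matrisome |
| Proteoglycans | Core matrisome |
| ECM-affiliated Proteins | Matrisome-associated |
| ECM Regulators | Matrisome-associated |
| Secreted Factors | Matrisome-associated |

Rows with no reference hit become `Non-matrisome`/`Non-matrisome`; the
pair is never mixed. This mapping is enforced twice: reference files that
violate it are refused at load time, and the annotator only ever copies a
validated entry's stored pair.

## Reference lists and validation

Reference lists are consumed as data in a flat CSV schema (one row per
gene; `:`-delimited identifier-list cells for NCBI gene, UniProt, Ensembl,
ZFIN, FlyBase, WormBase IDs and worm common names). Validation enforces,
mechanically, the invariants a curated list must satisfy:

* category ↔ division consistency (above);
* non-empty gene symbols, no empty identifier strings;
* species-specific namespaces only for their species (e.g. ZFIN only for
  zebrafish);
* a normalized identifier key shared by two entries with **different**
  classifications is an error (the load is refused); shared keys with the
  **same** classification are a warning only, and the first-loaded entry
  wins for provenance reporting — shared symbols and accessions occur in
  real lists and the classification is what downstream consumes.

How an official list resolves a key shared between two categories is a
curation question this package cannot decide; refusing the load makes the
conflict visible instead of silently picking a winner.

The bundled references are *synthetic* fixtures: 12 entries per species,
two per category, every namespace populated, built from well-known ECM
genes. They exercise every code path but are in no way a complete
matrisome; real analyses should convert an official list with
`scripts/convert_official_lists.py`.

## Identifier normalization and matching

All matching happens on normalized keys: trimmed, upper-cased, UniProt
isoform suffixes (`-2`) stripped when the prefix matches the UniProt
accession shape, Ensembl-style trailing versions (`.5`) stripped.
Hyphenated gene symbols (`emb-9`) are structurally distinguishable from
isoform-suffixed accessions and pass through intact. Case-insensitive
matching is deliberate: human symbols are upper-case, mouse symbols
title-case, and datasets mix conventions freely.

Multi-identifier cells split on `;`, `,` and `|`, preserving order; the
first sub-identifier present in the reference decides the row (the
proteomics "leading protein" convention). No majority voting, no fuzzy
matching, no cross-species ortholog mapping.

The index is a hash map from every normalized alias to its entry; a
brute-force row × entry × alias scan is kept in the test suite as an
independent oracle and the two are verified to agree on hundreds of random
fixtures.

## Number-format sniffing

Input cells are read as text and each column is classified once, by the
fraction of its non-empty cells matching a format (threshold 90%, chosen
to tolerate sporadic footnote cells without flipping a numeric column):

* dot-decimal numerics (including scientific notation) → coercible;
* percent-formatted values (`99%`) → **never** coercible; summing values
  that carry a unit is meaningless, so such columns are excluded from
  tabulation;
* single-comma values that are not 3-digit grouping (`3,14`) → coercible
  comma decimals;
* 3-digit-grouped values (`1,204`) → non-coercible with a logged warning:
  silently parsing `1,204` as 1.204 would be worse than excluding the
  column.

Classification is a pure function of the multiset of cell values, so it is
invariant under row permutation and blank-row padding. Missing cells in
coercible columns contribute 0 to sums and are counted in the log —
spreadsheet-style semantics for count data, stated loudly rather than
hidden.

## Tabulation

`matrianalyze` sums every coercible column per division and per category.
The output schema is fixed — a division block (3 rows) then a category
block (7 rows), zero-member annotations included with sum 0 — so outputs
are diffable across datasets. A single table with both blocks (rather than
two files) keeps the division/category identities checkable in one place;
the `Non-matrisome` label therefore appears once per block. Sums are
reported at full precision; integer columns stay integers. Conservation
identities (division sums = column total; core = its three categories;
associated = its three categories) hold exactly for integer inputs and to
float-summation precision (~1e-12 relative) for decimal columns.

## Charts

Chart construction is split from rendering: each chart is a
JSON-serializable spec carrying the groups, the fixed palette and the
derived geometry, then a matplotlib renderer draws it. The palette maps
each division/category label to one fixed hex color, identical across
charts, datasets and species — the contract is consistency, not specific
hues, and the palette can be overridden per call.

* matriring fractions are count/total over non-zero groups and sum to 1.
* matristar: angular width ∝ molecule count, radial height ∝ the
  aggregate value, both scaled linearly to the unit disc *per chart*
  (cross-chart comparability of bar heights is traded for full use of the
  radial range; the normalization is recorded in the spec hints).
* matriflow weights are the (grouping value × category) contingency table;
  per source they sum to the source's row count.

Rendering is deterministic (fixed figure size, DPI and fonts; no
timestamp in PDF metadata), so golden-file byte comparisons are possible.
`show=False` returns the figure object unwritten, for downstream
customization.

## Synthetic data generator

`matrisomekit.simulate` emulates the tool's canonical input — a label-free
proteomics results table: an identifier column drawing matrisome rows
uniformly from all reference aliases (random letter case, 15% multi-ID
cells with a decoy partner) and decoy identifiers guaranteed absent from
the reference for the rest; negative-binomial spectral counts (r=2,
p=0.1, mean ≈ 18 spectra — overdispersed counts typical of label-free
data); a uniform 10–300 kDa molecular-mass column with one decimal; and an
identification-probability column formatted as percentages (95–100%, as a
filtered search would report). Defaults are 200 rows, 3 samples, 30%
matrisome content — a plausible ECM-enriched proteome. Expression
(log-normal abundances) and exome-count (Poisson counts + subtype labels)
variants cover the transcriptomic and genomic input shapes.

What the generator does **not** emulate: real identifier noise
(obsolete accessions, contaminant entries), correlated abundances between
samples, missingness structure, or genuinely ambiguous identifiers.
Passing tests therefore demonstrate the correctness of matching,
tabulation and chart arithmetic — not the biological completeness of any
reference list.

## Problem sizes and numerical choices

The test suite verifies the oracle-equivalence and conservation properties
on 200 random fixtures each (up to 1,000 and 200 rows respectively) and
scales the end-to-end pipeline check to 100,000 rows, which completes in
roughly a second; the acceptance script uses 50 fixtures per property.
Sorting uses plain codepoint order on the upper-cased identifier — a
deliberate, documented collation choice for mixed digit/letter IDs.
Ties (duplicate identifiers) keep input order (stable sort).

## Known limitations

* `.rds` input needs the optional `pyreadr` extra; Excel formats and
  compressed inputs are out of scope.
* Skyline support reads a minimal protein-level subset (elements named
  `protein`/`peptide_list`, identifier from `name`/`accession`/`label` in
  that order, peptide descendants counted); the full Skyline document
  model is not parsed.
* GO:CC annotation uses a user-supplied local two-column mapping; no live
  ontology queries. The bundled mapping is a tiny synthetic fixture.
* No statistical testing or normalization — tabulations are meant to feed
  the user's statistics environment.
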