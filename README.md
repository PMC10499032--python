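# matrisomekit

Annotation, tabulation and visualization of extracellular-matrix (ECM)
components in tabular omics datasets.

The **matrisome** is the compendium of all genes encoding ECM and
ECM-associated proteins of an organism. Matrisome genes carry a two-level
classification: a *division* — **core matrisome** (structural components)
or **matrisome-associated** (non-structural components) — and one of six
*categories*: ECM glycoproteins, collagens and proteoglycans (core);
ECM-affiliated proteins, ECM regulators and secreted factors (associated).
The category determines the division exactly.

`matrisomekit` takes any tabular omics dataset (proteomics spectral counts,
bulk or single-cell RNA-seq, exome mutation counts, ...) with a header row
and an identifier column, matches the identifiers against a per-species
matrisome reference list, and:

1. **annotates** each row with its matrisome division and category
   (non-matching rows become `Non-matrisome`), optionally adding GO
   Cellular Component terms from a local mapping;
2. **tabulates** every numerically coercible column by division and by
   category (percent-formatted columns are excluded: their unit makes a
   plain sum meaningless);
3. **charts** the composition as bar charts (*matribars*), donuts
   (*matrirings*), polar bar charts (*matristars*) and alluvial diagrams
   (*matriflows*), with one fixed color per classification across all
   datasets and species.

Five organisms are supported — human, mouse, zebrafish, fruit fly and
nematode — with identifier matching across gene symbols, NCBI gene and
UniProt IDs for all species, plus Ensembl gene IDs (human/mouse), ZFIN
(zebrafish), FlyBase (fly), and WormBase IDs / common gene names (worm).
Matching is case-insensitive and tolerates UniProt isoform suffixes
(`P02452-2`), Ensembl version suffixes, and multi-ID cells
(`P02452;Q9XYZ1` — the first identifier found in the reference wins).

The package ships small *synthetic* per-species reference fixtures
(`test-human`, `test-mouse`, `test-zebrafish`, `test-fly`, `test-worm`;
12 entries each, two per category) for development and testing. Official
matrisome lists can be converted to the same CSV schema with
`scripts/convert_official_lists.py`.

## Worked example

```python
from matrisomekit import load_reference, matriannotate, matrianalyze
from matrisomekit.simulate import generate_proteomics_table

ref = load_reference("test-human")
table = generate_proteomics_table(n_rows=8, n_samples=2,
                                  matrisome_fraction=0.5, seed=7)
ann = matriannotate(table, "Protein IDs", "human", ref)
print(ann.df.to_string(index=False))
```

```
    Protein IDs Annotated Matrisome Division Annotated Matrisome Category Total Spectra Sample 1 Total Spectra Sample 2 Molecular Weight (kDa) Identification Probability
           4313         Matrisome-associated               ECM Regulators                     14                     26                   75.7                       100%
          Anxa2         Matrisome-associated      ECM-affiliated Proteins                     24                     61                  220.5                       100%
          CVC46                Non-matrisome                Non-matrisome                     14                     41                   14.1                       100%
ENSG00000102265         Matrisome-associated               ECM Regulators                     19                     14                  192.3                       100%
          LMN55                Non-matrisome                Non-matrisome                     34                     30                  158.8                        99%
         P02452               Core matrisome                    Collagens                      1                     12                  131.5                       100%
          TFZ44                Non-matrisome                Non-matrisome                      8                     10                  240.0                        98%
          YAL81                Non-matrisome                Non-matrisome                     16                     12                  246.4                       100%
```

Rows are sorted alphabetically by identifier; the annotation columns are
prepended and the original columns keep their order. Note the matching
across namespaces and case: `4313` is the NCBI gene ID of MMP2, `Anxa2`
(mouse-style casing) hits the human ANXA2 entry, `ENSG00000102265` is
TIMP1's Ensembl gene ID, and `P02452` is COL1A1's UniProt accession.

```python
tab = matrianalyze(ann)
print(tab.df.to_string(index=False))
```

```
  Matrisome Annotations  Total Spectra Sample 1  Total Spectra Sample 2  Molecular Weight (kDa)
         Core matrisome                       1                      12                   131.5
   Matrisome-associated                      57                     101                   488.5
          Non-matrisome                      72                      93                   659.3
      ECM Glycoproteins                       0                       0                     0.0
              Collagens                       1                      12                   131.5
          Proteoglycans                       0                       0                     0.0
ECM-affiliated Proteins                      24                      61                   220.5
         ECM Regulators                      33                      40                   268.0
       Secreted Factors                       0                       0                     0.0
          Non-matrisome                      72                      93                   659.3
```

Each coercible column is summed per annotation: in Sample&nbsp;1,
1 + 57 + 72 = 130 spectra — exactly the column total — and the category
block re-partitions the same totals (rows 4–10). The percent-formatted
`Identification Probability` column was excluded; the plain-number
molecular-mass column *is* tabulated even though summing masses is rarely
meaningful — column relevance is the user's call, mirroring standard
practice for this kind of tool.

The same objects feed the chart layer:

```python
from matrisomekit import summary_counts, matriring, render
render(matriring(summary_counts(ann), "categories"), "ring.pdf")
fig = render(matriring(summary_counts(ann), "divisions"), show=False)  # customize
```

## Command line

```sh
matrisomekit fixture --kind proteomics --rows 200 --seed 1 --out-dir data/
matrisomekit analyze --input data/proteomics_fixture.csv \
    --id-column "Protein IDs" --species human --out-dir results/ --bundle
```

`annotate` writes the annotated CSV plus a matribar PDF; `analyze`
additionally writes the tabulation CSV; `plot` re-draws any chart from an
annotated CSV; `fixture` generates synthetic test data. Every run writes a
`manifest.json` with file lists, row counts and the match rate; inputs
over 100 MB (configurable) are refused with a pointer to the library API.

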