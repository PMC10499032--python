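#!/usr/bin/env python
"""One-off converter: official matrisome list spreadsheets -> reference CSV.

The per-species matrisome lists published on the Matrisome Project website
come as spreadsheets with per-project column layouts. This script maps such
a sheet (exported to CSV) onto the reference schema matrisomekit consumes:

    species, division, category, gene_symbol, ncbi_gene_ids, uniprot_ids,
    ensembl_ids, zfin_ids, flybase_ids, wormbase_ids, common_names

with ``:`` delimiting multi-value identifier cells. Column names in the
source are matched case-insensitively against the aliases below; adjust
the alias table for a layout it does not know. The output is validated by
loading it before writing, so a conversion that breaks a curation
invariant (e.g. a shared accession with two different categories) fails
loudly instead of producing a bad reference.

Not used by the test suite — the repo builds and tests against the bundled
synthetic fixtures without any download.

Usage:
    python scripts/convert_official_lists.py --in Hs_Matrisome.csv \
        --species human --out human_reference.csv
"""

from __future__ import annotations

import argparse
import csv
import re
import sys
from pathlib import Path

COLUMN_ALIASES = {
    "division": ["division", "matrisome division"],
    "category": ["category", "matrisome category"],
    "gene_symbol": ["gene symbol", "gene", "official gene symbol"],
    "ncbi_gene_ids": ["ncbi gene id", "entrez gene id", "ncbi_gene_id(s)", "gene id"],
    "uniprot_ids": ["uniprot ids", "uniprot_id(s)", "uniprot", "uniprot accession"],
    "ensembl_ids": ["ensembl gene id", "ensembl_gene_id(s)", "ensembl"],
    "zfin_ids": ["zfin id", "zfin_id(s)"],
    "flybase_ids": ["flybase id", "flybase_id(s)", "fbgn"],
    "wormbase_ids": ["wormbase id", "wormbase_id(s)", "wbgene"],
    "common_names": ["common gene name", "common name"],
}

OUT_COLUMNS = ["species", "division", "category", "gene_symbol", "ncbi_gene_ids",
               "uniprot_ids", "ensembl_ids", "zfin_ids", "flybase_ids",
               "wormbase_ids", "common_names"]

_SPLIT = re.compile(r"[:;,|\s]+")


def _find(headers: list[str], wanted: str) -> str | None:
    lowered = {h.lower().strip(): h for h in headers}
    for alias in COLUMN_ALIASES[wanted]:
        if alias in lowered:
            return lowered[alias]
    return None


def convert(src: Path, species: str, dst: Path) -> None:
    with open(src, newline="", encoding="utf-8-sig") as fh:
        reader = csv.DictReader(fh)
        headers = reader.fieldnames or []
        mapping = {out: _find(headers, out) for out in COLUMN_ALIASES}
        for required in ("division", "category", "gene_symbol"):
            if mapping[required] is None:
                sys.exit(f"error: no source column found for {required!r}; "
                         f"known aliases: {COLUMN_ALIASES[required]}")
        rows = []
        for row in reader:
            out = {"species": species}
            for col in OUT_COLUMNS[1:]:
                src_col = mapping.get(col)
                raw = (row.get(src_col) or "").strip() if src_col else ""
                if col.endswith("_ids") or col == "common_names":
                    raw = ":".join(t for t in _SPLIT.split(raw) if t)
                out[col] = raw
            rows.append(out)

    with open(dst, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=OUT_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)

    # validate by loading; a broken conversion should not survive silently
    from matrisomekit import load_reference
    ref = load_reference(dst, species=species)
    print(f"wrote {dst}: {len(ref.entries)} entries, {len(ref.index)} indexed keys")


def main():
    parser = argparse.ArgumentParser(description=__doc__,
                                     formatter_class=argparse.RawDescriptionHelpFormatter)
    parser.add_argument("--in", dest="src", type=Path, required=True)
    parser.add_argument("--species", required=True,
                        choices=["human", "mouse", "zebrafish", "fly", "worm"])
    parser.add_argument("--out", dest="dst", type=Path, required=True)
    args = parser.parse_args()
    convert(args.src, args.species, args.dst)


if __name__ == "__main__":
    main()
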