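"""The matriannotate operation: classify table rows against a matrisome list.

Each row's identifier cell is normalized (see :mod:`matrisomekit.identifiers`)
and the *first* sub-identifier that hits the reference index determines the
row's matrisome division and category; rows with no hit are classified
``Non-matrisome``/``Non-matrisome``. The output table prepends the
annotation columns to the original columns (original order preserved) and
sorts rows alphabetically by identifier text.

Optionally a local GO Cellular Component mapping adds a fourth annotation
column, to help users judge the nature of non-matrisome hits (secreted
serum proteins, cytoskeleton, ...). The mapping is a two-column TSV
(identifier, term) supplied by the user; no remote queries are made.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ParameterError, SchemaError
from .identifiers import normalize_identifier, normalize_token
from .reference import MatrisomeReference, NON_MATRISOME, canonical_species
from .tabular_io import OmicsTable

logger = logging.getLogger(__name__)

DIVISION_COLUMN = "Annotated Matrisome Division"
CATEGORY_COLUMN = "Annotated Matrisome Category"
GOCC_COLUMN = "Annotated Gene Ontology: Cellular Component"

ANNOTATION_COLUMNS = (DIVISION_COLUMN, CATEGORY_COLUMN, GOCC_COLUMN)

BUNDLED_GOCC = {
    "test-human-gocc": "test_gocc_human_synthetic.tsv",
}


@dataclass(frozen=True)
class MatchRecord:
    """Which alias, in which namespace, matched which reference entry."""

    alias: str
    namespace: str
    gene_symbol: str
    entry_position: int


@dataclass
class AnnotatedTable:
    """An :class:`OmicsTable` with matrisome annotation columns prepended.

    Column layout: ``[identifier, Division, Category (, GO:CC), original
    non-identifier columns in original order]``; rows are sorted ascending
    by identifier text (codepoint order on the upper-cased key).
    ``match_log`` is aligned with the (sorted) rows; ``None`` marks a
    non-matrisome row.
    """

    table: OmicsTable
    id_column: str
    species: str
    match_log: list[MatchRecord | None] = field(default_factory=list)

    @property
    def df(self) -> pd.DataFrame:
        return self.table.df

    @property
    def has_gocc(self) -> bool:
        return GOCC_COLUMN in self.table.headers

    @property
    def divisions(self) -> pd.Series:
        return self.table.df[DIVISION_COLUMN]

    @property
    def categories(self) -> pd.Series:
        return self.table.df[CATEGORY_COLUMN]

    @property
    def value_columns(self) -> list[str]:
        """The original (non-identifier, non-annotation) columns."""
        skip = {self.id_column, *ANNOTATION_COLUMNS}
        return [h for h in self.table.headers if h not in skip]

    @property
    def n_matched(self) -> int:
        return sum(rec is not None for rec in self.match_log)


def load_gocc_map(source: str | Path) -> dict[str, list[str]]:
    """Load a GO:CC mapping TSV (columns: identifier, term; header row).

    Keys are normalized with the same rule as reference aliases, so a
    lookup for ``alb`` finds terms stored under ``ALB``. Multiple rows per
    identifier accumulate terms in file order. ``test-human-gocc`` names a
    bundled synthetic fixture.
    """
    if isinstance(source, str) and source in BUNDLED_GOCC:
        source = Path(str(resources.files("matrisomekit").joinpath("data", "go", BUNDLED_GOCC[source])))
    go_map: dict[str, list[str]] = {}
    with open(source, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise SchemaError(f"{source}: GO:CC map needs two tab-separated columns with a header row")
        for row in reader:
            if len(row) < 2:
                continue
            key = normalize_token(row[0])
            if key:
                go_map.setdefault(key, []).append(row[1].strip())
    return go_map


def annotate_gocc(ids: list[str], go_map: dict[str, list[str]]) -> list[str]:
    """Per identifier, the semicolon-joined GO:CC terms of its first mapped key.

    Unmapped identifiers yield an empty string. Pure function.
    """
    out = []
    for raw in ids:
        terms = ""
        for key in normalize_identifier(raw):
            if key in go_map:
                terms = ";".join(go_map[key])
                break
        out.append(terms)
    return out


def _classify_cell(raw: str, ref: MatrisomeReference):
    """Return (division, category, MatchRecord|None) for one identifier cell."""
    for key in normalize_identifier(raw):
        hit = ref.lookup(key)
        if hit is not None:
            entry, namespace = hit
            pos = ref.index[key][0]
            return entry.division, entry.category, MatchRecord(
                alias=key, namespace=namespace, gene_symbol=entry.gene_symbol,
                entry_position=pos)
    return NON_MATRISOME, NON_MATRISOME, None


def matriannotate(
    table: OmicsTable,
    id_column: str,
    species: str,
    ref: MatrisomeReference,
    go_map: dict[str, list[str]] | None = None,
) -> AnnotatedTable:
    """Annotate a table with matrisome divisions and categories.

    Parameters
    ----------
    table
        Input omics table (cells as text).
    id_column
        Header of the column holding gene/protein identifiers. Multi-ID
        cells (``P02452;Q9XYZ1``) are resolved to the first sub-identifier
        found in the reference.
    species
        Species tag; must match ``ref.species``.
    ref
        A loaded :class:`~matrisomekit.reference.MatrisomeReference`.
    go_map
        Optional GO:CC mapping (see :func:`load_gocc_map`); when given, a
        GO:CC column is added for every mapped identifier.

    Returns an :class:`AnnotatedTable` with exactly as many rows as the
    input (blank identifier cells annotate as Non-matrisome and are
    logged). If no identifier at all maps, the operation still succeeds
    but emits a "no identifiers mapped" warning so callers can prompt the
    user to review input choices (wrong column or species, typically).
    """
    if id_column not in table.headers:
        raise ParameterError(f"id_column {id_column!r} is not a header of the input table")
    species = canonical_species(species)
    if ref.species != species:
        raise ParameterError(
            f"reference is for species {ref.species!r}, but {species!r} was requested")

    ids = [str(v) for v in table.df[id_column].tolist()]
    n_blank = sum(1 for v in ids if not v.strip())
    if n_blank:
        logger.warning("%d blank identifier cell(s); annotated as Non-matrisome", n_blank)

    classified = [_classify_cell(v, ref) for v in ids]
    divisions = [c[0] for c in classified]
    categories = [c[1] for c in classified]
    match_log = [c[2] for c in classified]

    data: dict[str, list[str]] = {id_column: ids,
                                  DIVISION_COLUMN: divisions,
                                  CATEGORY_COLUMN: categories}
    if go_map is not None:
        data[GOCC_COLUMN] = annotate_gocc(ids, go_map)
    renamed = {}
    for h in table.headers:
        if h == id_column:
            continue
        out_name = h
        if h in data:  # input already carries a column named like an annotation column
            out_name = f"{h} (input)"
            renamed[h] = out_name
        data[out_name] = [str(v) for v in table.df[h].tolist()]
    if renamed:
        logger.warning("renamed input column(s) clashing with annotation columns: %s", renamed)

    out = pd.DataFrame(data, dtype=object)
    order = sorted(range(len(ids)), key=lambda i: ids[i].strip().upper())
    out = out.iloc[order].reset_index(drop=True)
    match_log = [match_log[i] for i in order]

    n_matched = sum(rec is not None for rec in match_log)
    if n_matched == 0 and len(ids) > 0:
        warnings.warn(
            "no identifiers mapped to the matrisome reference; review input "
            "choices (identifier column and species)", stacklevel=2)
    logger.info("annotated %d rows: %d matrisome, %d non-matrisome",
                len(ids), n_matched, len(ids) - n_matched)

    annotated = OmicsTable(df=out, provenance={**table.provenance,
                                               "annotated": True, "species": species})
    return AnnotatedTable(table=annotated, id_column=id_column, species=species,
                          match_log=match_log)
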