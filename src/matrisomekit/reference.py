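"""Per-species matrisome reference lists: loading, validation, indexing.

The matrisome is the compendium of genes encoding extracellular-matrix and
ECM-associated proteins. Each gene carries a two-level classification:

* division — ``Core matrisome`` (structural components) or
  ``Matrisome-associated`` (non-structural components);
* category — one of six: ECM Glycoproteins, Collagens, Proteoglycans
  (core), ECM-affiliated Proteins, ECM Regulators, Secreted Factors
  (associated).

The category determines the division exactly; that mapping is enforced at
load time and exposed via :func:`category_division_map`.

Reference lists are consumed as data in a simple CSV schema (one row per
gene, identifier-list cells delimited by ``:``). Small synthetic per-species
fixtures are bundled under tags ``test-human``, ``test-mouse``,
``test-zebrafish``, ``test-fly`` and ``test-worm``; official lists from the
Matrisome Project website can be converted to the same schema with
``scripts/convert_official_lists.py``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import ReferenceValidationError, SchemaError
from .identifiers import normalize_token

CORE = "Core matrisome"
ASSOCIATED = "Matrisome-associated"
NON_MATRISOME = "Non-matrisome"

DIVISIONS = (CORE, ASSOCIATED)

CATEGORIES = (
    "ECM Glycoproteins",
    "Collagens",
    "Proteoglycans",
    "ECM-affiliated Proteins",
    "ECM Regulators",
    "Secreted Factors",
)

_CATEGORY_TO_DIVISION = {
    "ECM Glycoproteins": CORE,
    "Collagens": CORE,
    "Proteoglycans": CORE,
    "ECM-affiliated Proteins": ASSOCIATED,
    "ECM Regulators": ASSOCIATED,
    "Secreted Factors": ASSOCIATED,
}

# Tolerated spelling variants, compared after lower-casing and whitespace
# collapse. Anything else is a schema error.
_CATEGORY_VARIANTS = {
    "ecm glycoproteins": "ECM Glycoproteins",
    "collagens": "Collagens",
    "proteoglycans": "Proteoglycans",
    "ecm-affiliated proteins": "ECM-affiliated Proteins",
    "ecm-affiliated": "ECM-affiliated Proteins",
    "ecm affiliated proteins": "ECM-affiliated Proteins",
    "ecm regulators": "ECM Regulators",
    "secreted factors": "Secreted Factors",
}
_DIVISION_VARIANTS = {
    "core matrisome": CORE,
    "matrisome-associated": ASSOCIATED,
    "matrisome associated": ASSOCIATED,
}

SPECIES = ("human", "mouse", "zebrafish", "fruit_fly", "nematode")

# Command-line friendly aliases.
SPECIES_ALIASES = {
    "human": "human",
    "mouse": "mouse",
    "zebrafish": "zebrafish",
    "fruit_fly": "fruit_fly",
    "fly": "fruit_fly",
    "drosophila": "fruit_fly",
    "nematode": "nematode",
    "worm": "nematode",
    "celegans": "nematode",
}

# Species-specific identifier namespaces; gene symbols, NCBI gene IDs and
# UniProt accessions are accepted for every species.
_SPECIES_NAMESPACES = {
    "human": ("ensembl_gene",),
    "mouse": ("ensembl_gene",),
    "zebrafish": ("zfin",),
    "fruit_fly": ("flybase",),
    "nematode": ("wormbase", "common_name"),
}

_GENERAL_NAMESPACES = ("gene_symbol", "ncbi_gene", "uniprot")

# CSV column -> namespace tag for list-valued identifier columns.
_ID_COLUMNS = {
    "ncbi_gene_ids": "ncbi_gene",
    "uniprot_ids": "uniprot",
    "ensembl_ids": "ensembl_gene",
    "zfin_ids": "zfin",
    "flybase_ids": "flybase",
    "wormbase_ids": "wormbase",
    "common_names": "common_name",
}

_REQUIRED_COLUMNS = ("species", "division", "category", "gene_symbol")

_LIST_DELIM = ":"

BUNDLED_REFERENCES = {
    "test-human": ("human", "test_human_synthetic.csv"),
    "test-mouse": ("mouse", "test_mouse_synthetic.csv"),
    "test-zebrafish": ("zebrafish", "test_zebrafish_synthetic.csv"),
    "test-fly": ("fruit_fly", "test_fly_synthetic.csv"),
    "test-worm": ("nematode", "test_worm_synthetic.csv"),
}


def bundled_tag_for_species(species: str) -> str:
    """The bundled synthetic-fixture tag for a (canonical) species."""
    species = canonical_species(species)
    for tag, (tag_species, _) in BUNDLED_REFERENCES.items():
        if tag_species == species:
            return tag
    raise SchemaError(f"no bundled reference for species {species!r}")  # pragma: no cover


def canonical_species(tag: str) -> str:
    """Resolve a species tag or alias to its canonical name."""
    try:
        return SPECIES_ALIASES[str(tag).strip().lower().replace(" ", "_")]
    except KeyError:
        raise SchemaError(f"unknown species {tag!r}; expected one of {sorted(SPECIES_ALIASES)}") from None


def category_division_map() -> dict[str, str]:
    """The fixed six-key mapping from matrisome category to division."""
    return dict(_CATEGORY_TO_DIVISION)


@dataclass(frozen=True)
class MatrisomeEntry:
    """One matrisome gene/protein with its classification and aliases."""

    species: str
    division: str
    category: str
    gene_symbol: str
    ncbi_gene_ids: tuple[str, ...] = ()
    uniprot_ids: tuple[str, ...] = ()
    species_specific_ids: tuple[tuple[str, str], ...] = ()  # (namespace, id)

    def aliases(self) -> Iterable[tuple[str, str]]:
        """Yield (namespace, raw alias) pairs, gene symbol first."""
        yield "gene_symbol", self.gene_symbol
        for i in self.ncbi_gene_ids:
            yield "ncbi_gene", i
        for i in self.uniprot_ids:
            yield "uniprot", i
        yield from self.species_specific_ids


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_reference`.

    ``issues`` holds (severity, entry locator, message) triples where
    severity is ``"error"`` or ``"warning"``.
    """

    issues: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(sev == "error" for sev, _, _ in self.issues)

    def errors(self) -> list[tuple[str, str, str]]:
        return [i for i in self.issues if i[0] == "error"]

    def warnings(self) -> list[tuple[str, str, str]]:
        return [i for i in self.issues if i[0] == "warning"]


@dataclass
class MatrisomeReference:
    """A validated, indexed per-species matrisome list.

    ``index`` maps every normalized alias key to ``(entry position,
    namespace of the matching alias)``. Benign collisions (two entries
    sharing an alias with identical classification) resolve to the
    first-loaded entry; conflicting collisions are refused at load time.
    """

    species: str
    entries: list[MatrisomeEntry]
    index: dict[str, tuple[int, str]]

    def lookup(self, key: str) -> tuple[MatrisomeEntry, str] | None:
        """Return (entry, namespace) for a normalized key, or None."""
        hit = self.index.get(key)
        if hit is None:
            return None
        pos, namespace = hit
        return self.entries[pos], namespace

    def __len__(self) -> int:
        return len(self.entries)


def _normalize_category(raw: str, locator: str) -> str:
    key = " ".join(str(raw).split()).lower()
    try:
        return _CATEGORY_VARIANTS[key]
    except KeyError:
        raise SchemaError(f"{locator}: unknown matrisome category {raw!r}") from None


def _normalize_division(raw: str, locator: str) -> str:
    key = " ".join(str(raw).split()).lower()
    try:
        return _DIVISION_VARIANTS[key]
    except KeyError:
        raise SchemaError(f"{locator}: unknown matrisome division {raw!r}") from None


def _split_list_cell(cell: str) -> tuple[str, ...]:
    return tuple(t.strip() for t in str(cell).split(_LIST_DELIM) if t.strip())


def validate_reference(entries: list[MatrisomeEntry]) -> ValidationReport:
    """Mechanically enforce the curation invariants on a list of entries.

    Violations are reported, never thrown: conflicting classifications for a
    shared normalized key are errors; identical-classification collisions
    are warnings (shared symbols and accessions occur in real lists).
    """
    report = ValidationReport()
    seen: dict[str, tuple[int, str, str]] = {}  # key -> (pos, division, category)
    for pos, entry in enumerate(entries):
        loc = f"entry {pos} ({entry.gene_symbol or '<blank>'})"
        if entry.species not in SPECIES:
            report.issues.append(("error", loc, f"unknown species {entry.species!r}"))
            continue
        if not entry.gene_symbol or not entry.gene_symbol.strip():
            report.issues.append(("error", loc, "gene_symbol is empty"))
        if entry.category not in _CATEGORY_TO_DIVISION:
            report.issues.append(("error", loc, f"unknown category {entry.category!r}"))
        elif _CATEGORY_TO_DIVISION[entry.category] != entry.division:
            report.issues.append(
                ("error", loc,
                 f"category {entry.category!r} requires division "
                 f"{_CATEGORY_TO_DIVISION[entry.category]!r}, got {entry.division!r}"))
        legal = set(_GENERAL_NAMESPACES) | set(_SPECIES_NAMESPACES.get(entry.species, ()))
        for namespace, alias in entry.aliases():
            if alias is not None and not str(alias).strip():
                report.issues.append(("error", loc, f"empty identifier in namespace {namespace}"))
                continue
            if namespace not in legal:
                report.issues.append(
                    ("error", loc, f"namespace {namespace!r} is not legal for species {entry.species}"))
                continue
            key = normalize_token(alias)
            if not key:
                continue
            prev = seen.get(key)
            if prev is None:
                seen[key] = (pos, entry.division, entry.category)
            elif prev[0] != pos:
                if (prev[1], prev[2]) != (entry.division, entry.category):
                    report.issues.append(
                        ("error", loc,
                         f"conflicting classification for key {key!r}: entry {prev[0]} is "
                         f"{prev[1]}/{prev[2]}, this entry is {entry.division}/{entry.category}"))
                else:
                    report.issues.append(
                        ("warning", loc, f"key {key!r} also exposed by entry {prev[0]} (same classification)"))
    return report


def _build_index(entries: list[MatrisomeEntry]) -> dict[str, tuple[int, str]]:
    index: dict[str, tuple[int, str]] = {}
    for pos, entry in enumerate(entries):
        for namespace, alias in entry.aliases():
            key = normalize_token(alias)
            if key and key not in index:  # first-loaded entry wins on benign collisions
                index[key] = (pos, namespace)
    return index


def _bundled_path(tag: str) -> tuple[str, Path]:
    species, filename = BUNDLED_REFERENCES[tag]
    path = resources.files("matrisomekit").joinpath("data", "references", filename)
    return species, Path(str(path))


def load_reference(source: str | Path, species: str | None = None) -> MatrisomeReference:
    """Load, validate and index a matrisome reference list.

    Parameters
    ----------
    source
        A bundled fixture tag (``test-human`` ...) or a path to a CSV in
        the documented schema (columns ``species, division, category,
        gene_symbol, ncbi_gene_ids, uniprot_ids, ensembl_ids, zfin_ids,
        flybase_ids, wormbase_ids, common_names``; list cells delimited by
        ``:``).
    species
        Expected species tag; defaults to the bundled tag's species, and is
        mandatory for file sources. Rows for a different species are a
        schema error.

    Raises
    ------
    SchemaError
        Missing required column, unknown label, or species mismatch.
    ReferenceValidationError
        The file parsed but violates a curation invariant (e.g. a key
        shared by entries with conflicting classifications).
    """
    if isinstance(source, str) and source in BUNDLED_REFERENCES:
        tag_species, path = _bundled_path(source)
        species = canonical_species(species) if species is not None else tag_species
        if species != tag_species:
            raise SchemaError(f"bundled reference {source!r} is for {tag_species}, not {species}")
    else:
        path = Path(source)
        if species is None:
            raise SchemaError("species is required when loading a reference from a file path")
        species = canonical_species(species)

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty reference file")
        missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        rows = list(reader)

    entries: list[MatrisomeEntry] = []
    for i, row in enumerate(rows):
        loc = f"{path.name} row {i + 2}"  # 1-based, after header
        row_species = canonical_species(row["species"])
        if row_species != species:
            raise SchemaError(f"{loc}: species {row['species']!r} does not match requested {species!r}")
        category = _normalize_category(row["category"], loc)
        division = _normalize_division(row["division"], loc)
        specific: list[tuple[str, str]] = []
        for col, namespace in _ID_COLUMNS.items():
            if namespace in ("ncbi_gene", "uniprot"):
                continue
            for alias in _split_list_cell(row.get(col, "")):
                specific.append((namespace, alias))
        entries.append(MatrisomeEntry(
            species=row_species,
            division=division,
            category=category,
            gene_symbol=row["gene_symbol"].strip(),
            ncbi_gene_ids=_split_list_cell(row.get("ncbi_gene_ids", "")),
            uniprot_ids=_split_list_cell(row.get("uniprot_ids", "")),
            species_specific_ids=tuple(specific),
        ))

    report = validate_reference(entries)
    if not report.ok:
        raise ReferenceValidationError(report)
    return MatrisomeReference(species=species, entries=entries, index=_build_index(entries))
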