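"""Reading and writing the tabular formats the toolkit accepts.

The universal in-memory currency is :class:`OmicsTable`: a pandas DataFrame
of *text* cells with unique non-empty headers plus provenance about how the
file was parsed. Keeping cells as text at read time lets number-format
sniffing (:func:`sniff_number_format`) decide per column whether values are
coercible to numbers — and with which decimal convention — instead of
trusting a global locale.

Supported inputs: ``.csv``, ``.tsv``, ``.txt``, ``.tabular`` (header row
mandatory; delimiter by extension, then by sniffing), a minimal subset of
Skyline proteomics XML documents (``.sky``), and ``.rds`` when the optional
``pyreadr`` extra is installed. Output is plain UTF-8 CSV.
"""

from __future__ import annotations

import csv
import io
import logging
import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd

from .errors import TableFormatError

logger = logging.getLogger(__name__)

_SNIFF_LINES = 50
_AGREEMENT = 0.90  # fraction of non-empty cells that must agree on a format

_DOT_NUMBER = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")
_COMMA_DECIMAL = re.compile(r"^[+-]?\d+,\d+$")
_COMMA_GROUPING = re.compile(r"^[+-]?\d{1,3}(,\d{3})+$")
_PERCENT = re.compile(r"^[+-]?(\d+([.,]\d*)?|[.,]\d+)\s*%$")
_IDENTIFIER_LIKE = re.compile(r"^[A-Za-z][A-Za-z0-9_.:|;,\- ]*$")


@dataclass
class OmicsTable:
    """An omics data table: text cells, unique headers, provenance.

    ``df`` holds every cell as a string (missing cells are empty strings);
    numeric interpretation is deferred to :func:`coerce_numeric_columns`.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def headers(self) -> list[str]:
        return [str(c) for c in self.df.columns]

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def column(self, header: str) -> list[str]:
        return self.df[header].tolist()


@dataclass(frozen=True)
class NumberFormat:
    """Parse rule for one column, as decided by the sniffer."""

    decimal: Literal["dot", "comma"] | None
    percent: bool
    coercible: bool


@dataclass
class NumericClassification:
    """Per-header coercibility verdicts for a table.

    ``kinds`` maps header -> one of ``coercible``, ``non_coercible``,
    ``identifier_like``; ``formats`` maps header -> :class:`NumberFormat`.
    """

    kinds: dict[str, str]
    formats: dict[str, NumberFormat]

    def coercible_headers(self) -> list[str]:
        return [h for h, k in self.kinds.items() if k == "coercible"]


def _check_headers(headers: list[str]) -> None:
    seen: set[str] = set()
    for pos, h in enumerate(headers, start=1):
        if not str(h).strip():
            raise TableFormatError(f"empty header at column position {pos}")
        if h in seen:
            raise TableFormatError(f"duplicate header {h!r} at column position {pos}")
        seen.add(h)


def _sniff_delimiter(lines: list[str]) -> str:
    """Pick the delimiter giving the highest consistent column count."""
    best, best_score = ",", (0, 0)
    for delim in (",", "\t", ";"):
        counts = [len(next(csv.reader([ln], delimiter=delim))) for ln in lines if ln]
        if not counts:
            continue
        mode = max(set(counts), key=counts.count)
        consistency = counts.count(mode)
        score = (consistency if mode > 1 else 0, mode)
        if score > best_score:
            best, best_score = delim, score
    return best


_EXTENSION_DELIMS = {".csv": ",", ".tsv": "\t", ".tabular": "\t"}


def read_table(path: str | Path, format_hint: str | None = None) -> OmicsTable:
    """Read a delimited text file into an :class:`OmicsTable`.

    The delimiter is taken from ``format_hint`` (``"csv"``/``"tsv"`` or a
    literal delimiter), else from the file extension, else sniffed as the
    delimiter yielding the most consistent column count over the first 50
    lines. Cells are kept as raw text.

    Raises :class:`TableFormatError` on duplicate or empty headers (naming
    the 1-based column position) and ``UnicodeDecodeError`` on undecodable
    bytes. A file with headers but zero data rows yields an empty table
    with a warning.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")

    if format_hint in ("csv", ","):
        delim = ","
    elif format_hint in ("tsv", "tab", "\t"):
        delim = "\t"
    elif format_hint:
        delim = format_hint
    else:
        delim = _EXTENSION_DELIMS.get(path.suffix.lower())
        if delim is None:
            delim = _sniff_delimiter(text.splitlines()[:_SNIFF_LINES])

    rows = [r for r in csv.reader(io.StringIO(text), delimiter=delim)]
    rows = [r for r in rows if r != []]  # blank lines carry no cells
    if not rows:
        raise TableFormatError(f"{path}: no header row")
    headers = [h.strip() for h in rows[0]]
    _check_headers(headers)

    data = rows[1:]
    ncol = len(headers)
    for i, row in enumerate(data):
        if len(row) > ncol:
            raise TableFormatError(f"{path}: row {i + 2} has {len(row)} cells, header has {ncol}")
        if len(row) < ncol:
            data[i] = row + [""] * (ncol - len(row))
    if not data:
        warnings.warn(f"{path}: table has headers but zero data rows", stacklevel=2)

    df = pd.DataFrame(data, columns=headers, dtype=object) if data else pd.DataFrame(
        {h: pd.Series(dtype=object) for h in headers})
    prov = {"source": str(path), "delimiter": delim, "n_rows": len(df), "n_cols": ncol}
    logger.info("read %s: %d rows x %d columns (delimiter=%r)", path, len(df), ncol, delim)
    return OmicsTable(df=df, provenance=prov)


def sniff_number_format(values: list[str]) -> NumberFormat:
    """Decide how (whether) a column of text cells parses to numbers.

    Rules, applied to the non-empty cells:

    * >=90% match a dot-decimal numeric pattern -> dot decimal, coercible;
    * >=90% are percent-formatted (numeric prefix + ``%``) -> percent,
      never coercible (units make spreadsheet-style sums meaningless);
    * >=90% match a single-comma pattern that is *not* 3-digit grouping ->
      comma decimal, coercible (``3,14`` parses to 3.14);
    * anything else — including ambiguous thousands grouping such as
      ``1,204`` — is non-coercible.
    """
    cells = [str(v).strip() for v in values]
    cells = [c for c in cells if c]
    if not cells:
        return NumberFormat(decimal=None, percent=False, coercible=False)
    n = len(cells)
    if sum(bool(_DOT_NUMBER.match(c)) for c in cells) / n >= _AGREEMENT:
        return NumberFormat(decimal="dot", percent=False, coercible=True)
    if sum(bool(_PERCENT.match(c)) for c in cells) / n >= _AGREEMENT:
        return NumberFormat(decimal=None, percent=True, coercible=False)
    comma_only = sum(
        bool(_COMMA_DECIMAL.match(c)) and not _COMMA_GROUPING.match(c) for c in cells)
    if comma_only / n >= _AGREEMENT:
        return NumberFormat(decimal="comma", percent=False, coercible=True)
    if sum(bool(_COMMA_GROUPING.match(c)) for c in cells) / n >= _AGREEMENT:
        logger.warning("column looks like 3-digit-grouped numbers; treated as non-coercible")
    return NumberFormat(decimal=None, percent=False, coercible=False)


def coerce_numeric_columns(table: OmicsTable) -> NumericClassification:
    """Classify every column of a table as coercible / non-coercible / ID-like.

    Classification is order-free (a pure function of the multiset of cell
    values) and ignores empty cells, so appending blank rows never flips a
    verdict.
    """
    kinds: dict[str, str] = {}
    formats: dict[str, NumberFormat] = {}
    for h in table.headers:
        values = table.df[h].tolist()
        fmt = sniff_number_format(values)
        formats[h] = fmt
        if fmt.coercible:
            kinds[h] = "coercible"
        else:
            nonempty = [str(v).strip() for v in values if str(v).strip()]
            idlike = nonempty and sum(
                bool(_IDENTIFIER_LIKE.match(c)) for c in nonempty) / len(nonempty) >= _AGREEMENT
            kinds[h] = "identifier_like" if idlike else "non_coercible"
    return NumericClassification(kinds=kinds, formats=formats)


def parse_numeric(values: list[str], fmt: NumberFormat) -> pd.Series:
    """Parse a coercible column to floats; empty cells become NaN."""
    if not fmt.coercible:
        raise TableFormatError("parse_numeric called on a non-coercible column")
    s = pd.Series([str(v).strip() for v in values], dtype=object)
    if fmt.decimal == "comma":
        s = s.str.replace(",", ".", regex=False)
    s = s.replace("", None)
    return pd.to_numeric(s, errors="coerce")


def _local_name(tag: str) -> str:
    return tag.rsplit("}", 1)[-1].lower()


def read_skyline(path: str | Path) -> OmicsTable:
    """Extract protein identifiers and peptide counts from a Skyline XML file.

    Only a minimal protein-level subset of the Skyline document model is
    read: every element whose local name is ``protein`` (or
    ``peptide_list``) contributes one row, identified by the first
    available of its ``name``, ``accession`` or ``label`` attributes, with
    the number of ``peptide`` descendants as a numeric column.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise TableFormatError(f"{path}: not well-formed XML: {exc}") from exc
    rows = []
    for elem in tree.getroot().iter():
        if _local_name(elem.tag) in ("protein", "peptide_list"):
            ident = elem.get("name") or elem.get("accession") or elem.get("label") or ""
            n_pep = sum(1 for child in elem.iter() if _local_name(child.tag) == "peptide")
            rows.append((ident, str(n_pep)))
    if not rows:
        warnings.warn(f"{path}: no protein elements found; returning empty table", stacklevel=2)
    df = pd.DataFrame(rows, columns=["Protein", "Peptides"], dtype=object) if rows else pd.DataFrame(
        {"Protein": pd.Series(dtype=object), "Peptides": pd.Series(dtype=object)})
    return OmicsTable(df=df, provenance={"source": str(path), "format": "skyline"})


def read_rds(path: str | Path) -> OmicsTable:
    """Read a serialized R data.frame (requires the optional ``rds`` extra)."""
    try:
        import pyreadr  # noqa: PLC0415
    except ImportError as exc:
        raise TableFormatError(
            "reading .rds files requires the optional dependency pyreadr; "
            "install matrisomekit[rds]") from exc
    result = pyreadr.read_r(str(path))
    df = next(iter(result.values())).astype(object).fillna("")
    df = df.map(str)
    _check_headers([str(c) for c in df.columns])
    return OmicsTable(df=df, provenance={"source": str(path), "format": "rds"})


def write_csv(table, path: str | Path) -> None:
    """Write a table to UTF-8 CSV (header first, quoting only when needed).

    Accepts an :class:`OmicsTable`, anything with a ``.df`` DataFrame
    attribute (annotated and tabulation tables), or a bare DataFrame.
    Text-cell tables round-trip exactly through :func:`read_table`.
    """
    df = table.df if hasattr(table, "df") else table
    path = Path(path)
    # single-column tables quote every cell: an empty cell would otherwise
    # serialize to a blank line and be indistinguishable from no row at all
    quoting = csv.QUOTE_ALL if len(df.columns) == 1 else csv.QUOTE_MINIMAL
    df.to_csv(path, index=False, encoding="utf-8", quoting=quoting,
              lineterminator="\n")
    logger.info("wrote %s: %d rows x %d columns", path, len(df), len(df.columns))
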