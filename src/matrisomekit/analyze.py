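"""The matrianalyze operation: sum numeric columns by matrisome annotation.

Given an annotated table, every column the number-format sniffer deems
coercible is summed per matrisome division and per category, producing a
fixed-schema table whose rows are the matrisome classifications (division
block first, then the category block) and whose columns are the numeric
input columns. Percent-formatted columns are excluded — their unit makes a
plain sum meaningless — while any plain-number column is tabulated, even
when the sum is not biologically interpretable (a molecular-mass column,
say); choosing relevant columns is deliberately left to the user.

Conservation identities hold exactly for integer inputs: the three division
sums add up to the column total, the core categories add up to the core
division, and the associated categories add up to the associated division.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .annotate import AnnotatedTable
from .reference import ASSOCIATED, CATEGORIES, CORE, NON_MATRISOME
from .tabular_io import OmicsTable, coerce_numeric_columns, parse_numeric

logger = logging.getLogger(__name__)

ANNOTATIONS_COLUMN = "Matrisome Annotations"

DIVISION_ROWS = (CORE, ASSOCIATED, NON_MATRISOME)
CATEGORY_ROWS = CATEGORIES + (NON_MATRISOME,)

# Fixed output row order: divisions block, then categories block. The
# Non-matrisome label appears once per block (rows 3 and 10).
ANNOTATION_ROWS = DIVISION_ROWS + CATEGORY_ROWS

_CORE_CATEGORIES = ("ECM Glycoproteins", "Collagens", "Proteoglycans")
_ASSOCIATED_CATEGORIES = ("ECM-affiliated Proteins", "ECM Regulators", "Secreted Factors")


@dataclass
class TabulationTable:
    """Per-annotation column sums; one row per matrisome classification."""

    df: pd.DataFrame

    @property
    def value_columns(self) -> list[str]:
        return [c for c in self.df.columns if c != ANNOTATIONS_COLUMN]

    def division_block(self) -> pd.DataFrame:
        return self.df.iloc[: len(DIVISION_ROWS)]

    def category_block(self) -> pd.DataFrame:
        return self.df.iloc[len(DIVISION_ROWS):]


@dataclass
class CountSummary:
    """Row (molecule) counts per division and per category — not value sums."""

    division_counts: dict[str, int]
    category_counts: dict[str, int]
    n_rows: int


def matrianalyze(table: AnnotatedTable) -> TabulationTable:
    """Tabulate every coercible column of an annotated table by annotation.

    Missing cells in coercible columns contribute 0 to the sums (the count
    of such cells is logged). Annotation rows with zero members still
    appear, with sum 0, so the output schema is stable across datasets.
    With zero coercible columns the result contains only the annotation
    rows, and a warning is logged.
    """
    base = OmicsTable(df=table.df[table.value_columns], provenance={})
    classification = coerce_numeric_columns(base)
    coercible = classification.coercible_headers()
    if not coercible:
        logger.warning("no coercible columns found; tabulation has annotation rows only")

    out = pd.DataFrame({ANNOTATIONS_COLUMN: list(ANNOTATION_ROWS)})
    divisions = table.divisions
    categories = table.categories
    for h in coercible:
        values = parse_numeric(table.df[h].tolist(), classification.formats[h])
        n_missing = int(values.isna().sum())
        if n_missing:
            logger.warning("column %r: %d missing cell(s) treated as 0", h, n_missing)
        values = values.fillna(0.0)
        by_division = values.groupby(divisions.values).sum()
        by_category = values.groupby(categories.values).sum()
        col = [float(by_division.get(d, 0.0)) for d in DIVISION_ROWS]
        col += [float(by_category.get(c, 0.0)) for c in CATEGORY_ROWS]
        if all(v.is_integer() for v in col):
            col = [int(v) for v in col]
        out[h] = col
    logger.info("tabulated %d coercible column(s); excluded: %s", len(coercible),
                [h for h in table.value_columns if h not in coercible] or "none")
    return TabulationTable(df=out)


def summary_counts(table: AnnotatedTable) -> CountSummary:
    """Count rows (molecules) per division and per category.

    Order-free and pure; the counts behind the matribar charts.
    """
    div = table.divisions.value_counts()
    cat = table.categories.value_counts()
    return CountSummary(
        division_counts={d: int(div.get(d, 0)) for d in DIVISION_ROWS},
        category_counts={c: int(cat.get(c, 0)) for c in CATEGORY_ROWS},
        n_rows=table.table.n_rows,
    )


def conservation_check(tab: TabulationTable, atol: float = 0.0) -> Mapping[str, float]:
    """Max absolute deviation of each conservation identity across columns.

    Returns ``{"division_total": ..., "core": ..., "associated": ...}``;
    all three are 0 for integer inputs. Useful as a self-check after
    tabulating real data.
    """
    labels = tab.df[ANNOTATIONS_COLUMN].tolist()
    div_idx = {d: i for i, d in enumerate(ANNOTATION_ROWS[:3])}
    cat_idx = {c: i + 3 for i, c in enumerate(ANNOTATION_ROWS[3:])}
    assert labels == list(ANNOTATION_ROWS)
    worst = {"division_total": 0.0, "core": 0.0, "associated": 0.0}
    for h in tab.value_columns:
        col = tab.df[h].tolist()
        total_div = sum(col[div_idx[d]] for d in DIVISION_ROWS)
        total_cat = sum(col[i] for i in cat_idx.values())
        worst["division_total"] = max(worst["division_total"], abs(total_div - total_cat))
        worst["core"] = max(worst["core"], abs(
            col[div_idx[CORE]] - sum(col[cat_idx[c]] for c in _CORE_CATEGORIES)))
        worst["associated"] = max(worst["associated"], abs(
            col[div_idx[ASSOCIATED]] - sum(col[cat_idx[c]] for c in _ASSOCIATED_CATEGORIES)))
    return worst
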