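"""Matrisome composition charts: matribars, matrirings, matristars, matriflows.

Charts are first built as renderer-independent :class:`ChartSpec` objects
(JSON-serializable, convenient for golden-file tests), then drawn with a
small matplotlib renderer. Colors come from a fixed palette keyed on the
division/category label — the same label is the same color in every chart,
for every dataset and every species, so compositions remain comparable
across figures.

Chart kinds
-----------
* ``matribar`` — paired bar charts of molecule counts per division and per
  category (the annotate workflow's summary figure);
* ``matriring`` — a donut whose angular fractions are the share of each
  division or category in the dataset;
* ``matristar`` — a polar bar chart: angular width of each category segment
  is proportional to its molecule count, radial bar height to an aggregate
  value (e.g. mean expression in a cell cluster), both scaled linearly to
  the unit disc per chart;
* ``matriflow`` — an alluvial/Sankey-style chart of row counts flowing from
  the values of a grouping column (samples, clusters, ...) to matrisome
  categories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analyze import CATEGORY_ROWS, CountSummary, DIVISION_ROWS
from .annotate import AnnotatedTable, CATEGORY_COLUMN
from .errors import ChartDomainError, EmptyChartError, ParameterError
from .reference import CATEGORIES, NON_MATRISOME

# One fixed color per division and per category, independent of dataset and
# species. Overridable per call, but the default is the contract.
DEFAULT_PALETTE: dict[str, str] = {
    "Core matrisome": "#0D3B66",
    "Matrisome-associated": "#E8871E",
    "Non-matrisome": "#B0B0B0",
    "ECM Glycoproteins": "#13547A",
    "Collagens": "#2A9D8F",
    "Proteoglycans": "#80CED7",
    "ECM-affiliated Proteins": "#E76F51",
    "ECM Regulators": "#F4A261",
    "Secreted Factors": "#E9C46A",
}

Kind = Literal["matribar", "matriring", "matristar", "matriflow"]


@dataclass
class ChartSpec:
    """Renderer-independent description of one matrisome chart.

    ``groups`` holds ordered ``(label, value)`` pairs, or ``(source,
    target, weight)`` triples for matriflow. ``hints`` carries the derived
    geometry (angular fractions, radial heights) so tests can check the
    chart math without rendering.
    """

    kind: Kind
    groups: list[tuple]
    palette: dict[str, str]
    title: str = ""
    subtitle: str = ""
    hints: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    def color(self, label: str) -> str:
        return self.palette.get(label, "#808080")


def _merge_palette(palette: dict[str, str] | None) -> dict[str, str]:
    merged = dict(DEFAULT_PALETTE)
    if palette:
        merged.update(palette)
    return merged


def matribar(summary: CountSummary, title: str = "Matrisome composition",
             palette: dict[str, str] | None = None) -> ChartSpec:
    """Bar chart of molecule counts: divisions panel then categories panel."""
    groups = [(d, summary.division_counts.get(d, 0)) for d in DIVISION_ROWS]
    groups += [(c, summary.category_counts.get(c, 0)) for c in CATEGORY_ROWS]
    return ChartSpec(kind="matribar", groups=groups, palette=_merge_palette(palette),
                     title=title, hints={"panel_split": len(DIVISION_ROWS)})


def matriring(summary: CountSummary, level: Literal["divisions", "categories"] = "divisions",
              title: str = "", palette: dict[str, str] | None = None) -> ChartSpec:
    """Donut chart: each group's angular fraction is count / total."""
    if level == "divisions":
        counts = {d: summary.division_counts.get(d, 0) for d in DIVISION_ROWS}
    elif level == "categories":
        counts = {c: summary.category_counts.get(c, 0) for c in CATEGORY_ROWS}
    else:
        raise ParameterError(f"level must be 'divisions' or 'categories', got {level!r}")
    total = sum(counts.values())
    if total == 0:
        raise EmptyChartError("matriring needs at least one non-zero count")
    fractions = {lbl: n / total for lbl, n in counts.items() if n > 0}
    return ChartSpec(kind="matriring", groups=list(counts.items()),
                     palette=_merge_palette(palette),
                     title=title or f"Matrisome {level}",
                     hints={"level": level, "fractions": fractions})


def matristar(values: dict[str, float], counts: dict[str, int], title: str = "",
              palette: dict[str, str] | None = None) -> ChartSpec:
    """Polar bar chart: segment width ~ molecule count, height ~ aggregate value.

    ``values`` maps category label -> non-negative aggregate (e.g. mean
    expression); ``counts`` maps the same labels -> molecule counts.
    Zero-count categories get zero-width segments and are excluded from
    rendering. Both normalizations (width by total count, height by the
    per-chart maximum value) are recorded in the spec hints.
    """
    allowed = set(CATEGORIES) | {NON_MATRISOME}
    unknown = set(values) - allowed
    if unknown:
        raise ParameterError(f"unknown categories: {sorted(unknown)}")
    if any(v < 0 for v in values.values()):
        raise ChartDomainError("matristar aggregate values must be non-negative")
    labels = [c for c in (*CATEGORIES, NON_MATRISOME) if c in values]
    total_count = sum(counts.get(c, 0) for c in labels)
    vmax = max((values[c] for c in labels), default=0.0)
    widths = {c: (counts.get(c, 0) / total_count if total_count else 0.0) for c in labels}
    heights = {c: (values[c] / vmax if vmax else 0.0) for c in labels}
    groups = [(c, float(values[c])) for c in labels]
    return ChartSpec(kind="matristar", groups=groups, palette=_merge_palette(palette),
                     title=title or "Matrisome categories",
                     hints={"angular_fraction": widths, "radial_height": heights,
                            "counts": {c: int(counts.get(c, 0)) for c in labels},
                            "width_normalization": "count / total count",
                            "height_normalization": "value / max value (per chart)"})


def matriflow(annotated: AnnotatedTable, grouping: str, title: str = "",
              palette: dict[str, str] | None = None) -> ChartSpec:
    """Alluvial chart: row counts flowing from a grouping column to categories.

    Flow weights are the contingency table of (grouping value, category);
    per source they sum to that source's row count.
    """
    if grouping not in annotated.table.headers:
        raise ParameterError(f"grouping column {grouping!r} is not a header of the table")
    sources = annotated.df[grouping].astype(str)
    categories = annotated.df[CATEGORY_COLUMN]
    counts = (
        annotated.df.groupby([sources, categories], sort=False).size()
    )
    triples = [(str(src), str(cat), int(n)) for (src, cat), n in counts.items()]
    triples.sort(key=lambda t: (t[0], _category_order(t[1])))
    source_totals: dict[str, int] = {}
    for src, _, n in triples:
        source_totals[src] = source_totals.get(src, 0) + n
    return ChartSpec(kind="matriflow", groups=triples, palette=_merge_palette(palette),
                     title=title or f"Matrisome categories by {grouping}",
                     hints={"grouping": grouping, "source_totals": source_totals})


def _category_order(label: str) -> int:
    order = (*CATEGORIES, NON_MATRISOME)
    return order.index(label) if label in order else len(order)


# ---------------------------------------------------------------------------
# Rendering


def _draw_matribar(spec: ChartSpec, fig) -> None:
    split = spec.hints.get("panel_split", 3)
    panels = [spec.groups[:split], spec.groups[split:]]
    titles = ["Divisions", "Categories"]
    for ax, groups, sub in zip(fig.subplots(1, 2, width_ratios=[1, 2]), panels, titles):
        labels = [g[0] for g in groups]
        heights = [g[1] for g in groups]
        ax.bar(range(len(groups)), heights, color=[spec.color(l) for l in labels])
        ax.set_xticks(range(len(groups)))
        ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=7)
        ax.set_ylabel("Molecules")
        ax.set_title(sub, fontsize=9)
    fig.suptitle(spec.title)


def _draw_matriring(spec: ChartSpec, fig) -> None:
    ax = fig.subplots()
    nonzero = [(lbl, v) for lbl, v in spec.groups if v > 0]
    ax.pie([v for _, v in nonzero],
           labels=[f"{lbl} ({v})" for lbl, v in nonzero],
           colors=[spec.color(lbl) for lbl, _ in nonzero],
           startangle=90, counterclock=False,
           wedgeprops={"width": 0.4, "edgecolor": "white"},
           textprops={"fontsize": 7})
    ax.set_title(spec.title)


def _draw_matristar(spec: ChartSpec, fig) -> None:
    ax = fig.add_subplot(projection="polar")
    widths = spec.hints["angular_fraction"]
    heights = spec.hints["radial_height"]
    theta = 0.0
    for lbl, _ in spec.groups:
        w = widths[lbl] * 2 * np.pi
        if w <= 0:
            continue
        ax.bar(theta + w / 2, heights[lbl], width=w, bottom=0.0,
               color=spec.color(lbl), edgecolor="white", linewidth=0.5)
        theta += w
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(spec.title, fontsize=9)


def _draw_matriflow(spec: ChartSpec, fig) -> None:
    ax = fig.subplots()
    sources = list(dict.fromkeys(t[0] for t in spec.groups))
    targets = list(dict.fromkeys(t[1] for t in spec.groups))
    total = sum(t[2] for t in spec.groups)
    gap = 0.02 * total
    src_base, tgt_base = {}, {}
    y = 0.0
    for s in sources:
        src_base[s] = y
        y += sum(t[2] for t in spec.groups if t[0] == s) + gap
    y = 0.0
    for t in targets:
        tgt_base[t] = y
        y += sum(tr[2] for tr in spec.groups if tr[1] == t) + gap
    src_off = dict.fromkeys(sources, 0.0)
    tgt_off = dict.fromkeys(targets, 0.0)
    for s, t, w in spec.groups:
        y0 = src_base[s] + src_off[s]
        y1 = tgt_base[t] + tgt_off[t]
        xs = np.linspace(0.15, 0.85, 50)
        ease = (1 - np.cos(np.pi * (xs - 0.15) / 0.7)) / 2
        top = y0 + (y1 - y0) * ease
        ax.fill_between(xs, top, top + w, color=spec.color(t), alpha=0.6, linewidth=0)
        src_off[s] += w
        tgt_off[t] += w
    for s in sources:
        h = sum(t[2] for t in spec.groups if t[0] == s)
        ax.fill_between([0.10, 0.15], src_base[s], src_base[s] + h, color="#444444")
        ax.text(0.09, src_base[s] + h / 2, str(s), ha="right", va="center", fontsize=7)
    for t in targets:
        h = sum(tr[2] for tr in spec.groups if tr[1] == t)
        ax.fill_between([0.85, 0.90], tgt_base[t], tgt_base[t] + h, color=spec.color(t))
        ax.text(0.91, tgt_base[t] + h / 2, str(t), ha="left", va="center", fontsize=7)
    ax.set_xlim(0, 1.3)
    ax.axis("off")
    ax.set_title(spec.title, fontsize=9)


_DRAWERS = {
    "matribar": _draw_matribar,
    "matriring": _draw_matriring,
    "matristar": _draw_matristar,
    "matriflow": _draw_matriflow,
}


def render(spec: ChartSpec, path: str | Path | None = None,
           format: Literal["pdf", "png"] = "pdf", show: bool = True):
    """Render a chart spec to PDF/PNG, or return the figure for customization.

    With ``show=True`` (default) the chart is written to ``path`` and
    nothing is returned. With ``show=False`` the matplotlib ``Figure`` is
    returned instead and no file is written — callers can restyle it and
    save it themselves. Output is deterministic: fixed size/DPI, and PDF
    metadata carries no timestamp, so the same spec renders to identical
    bytes.
    """
    fig = plt.figure(figsize=(8, 4.5), dpi=100)
    _DRAWERS[spec.kind](spec, fig)
    fig.tight_layout()
    if not show:
        return fig
    if path is None:
        raise ParameterError("render(show=True) requires an output path")
    path = Path(path)
    if format == "pdf":
        fig.savefig(path, format="pdf", metadata={"CreationDate": None})
    elif format == "png":
        fig.savefig(path, format="png", dpi=100)
    else:
        raise ParameterError(f"unsupported format {format!r}")
    plt.close(fig)
    return None
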