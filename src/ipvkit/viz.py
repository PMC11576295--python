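"""Radar-map layouts and rendering for IPV results.

Two chart types are produced: an item-level radar map per instrument
(items as rays, length proportional to center distance, facets as angular
sectors, dotted rings as the cd grid) and the nested scale-level map
(instrument circles offset from the chart center proportionally to their
aggregate cd, facet markers inside each circle, latent correlations
annotated between circles).

All geometry is a pure, deterministic function of the analysis result and
a style mapping; rendering twice from the same layout yields byte-identical
SVG.  Axis scaling is linear in cd.  Facet positions are meaningful only
within their own instrument circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .ipv import ItemCenterDistance, NestedIPVResult

__all__ = [
    "ItemChartLayout",
    "NestedChartLayout",
    "DEFAULT_STYLE",
    "layout_item_chart",
    "layout_nested_chart",
    "render",
]

DEFAULT_STYLE: dict = {
    "figsize": (6.0, 6.0),
    "ray_color": "#2b5d8a",
    "grid_color": "#999999",
    "circle_color": "#2b5d8a",
    "facet_color": "#b04a4a",
    "font_size": 8,
    "tick_step": 0.1,
    "alternate_offset": 0.35,  # fraction of tick_step added to every 2nd ray label radius
    "nested_offset_scale": 1.0,  # chart units per unit aggregate cd
    "nested_circle_radius": 0.09,
    "svg_hashsalt": "ipvkit",
}


@dataclass
class ItemChartLayout:
    items: pd.DataFrame  # item_id, facet, angle, radial, alternate
    facet_sectors: dict[str, tuple[float, float]]
    grid_radii: tuple[float, ...]
    title: str = ""


@dataclass
class NestedChartLayout:
    instruments: pd.DataFrame  # instrument, angle, offset, radius, aggregate_cd
    facets: pd.DataFrame  # facet, instrument, x, y
    correlations: pd.DataFrame  # inst_a, inst_b, value, x, y
    title: str = ""


def layout_item_chart(
    items: list[ItemCenterDistance],
    facets: dict[str, str] | None = None,
    style: dict | None = None,
    title: str = "",
) -> ItemChartLayout:
    """Place each item on a ray: facets occupy contiguous angular sectors
    sized by item count, items are evenly spaced within their sector, and
    the radial coordinate is the center distance (linear scale).  Every
    second item within a facet is marked ``alternate`` so the renderer can
    vary ray length for legibility."""
    if not items:
        raise ValueError("empty item list")
    style = {**DEFAULT_STYLE, **(style or {})}
    facets = facets or {it.item_id: "" for it in items}
    order: list[str] = []
    for it in items:
        f = facets.get(it.item_id, "")
        if f not in order:
            order.append(f)
    by_facet = {f: [it for it in items if facets.get(it.item_id, "") == f] for f in order}

    n_total = len(items)
    sectors: dict[str, tuple[float, float]] = {}
    rows = []
    start = 0.0
    for f in order:
        group = by_facet[f]
        width = 2 * math.pi * len(group) / n_total
        sectors[f] = (start, start + width)
        for k, it in enumerate(group):
            angle = start + width * (k + 0.5) / len(group)
            rows.append(
                {
                    "item_id": it.item_id,
                    "facet": f,
                    "angle": angle,
                    "radial": it.cd,
                    "alternate": bool(k % 2),
                }
            )
        start += width
    df = pd.DataFrame(rows)
    step = style["tick_step"]
    top = max(step, math.ceil(max(df["radial"].max(), 1e-9) / step) * step)
    grid = tuple(np.round(np.arange(step, top + step / 2, step), 10))
    return ItemChartLayout(items=df, facet_sectors=sectors, grid_radii=grid, title=title)


def layout_nested_chart(
    result: NestedIPVResult, style: dict | None = None, title: str = ""
) -> NestedChartLayout:
    """Nested scale-level map: one circle per instrument, center offset
    proportional to its aggregate cd (smallest cd nearest the chart
    center), angular slots assigned by ascending aggregate cd so the
    geometry depends on the numbers only.  Facet markers sit inside their
    instrument's circle at a radius proportional to the facet aggregate cd;
    latent correlations are annotated midway between circle pairs."""
    style = {**DEFAULT_STYLE, **(style or {})}
    summ = result.instrument_summaries
    insts = sorted(summ, key=lambda k: (summ[k].aggregate_cd, k))
    m = len(insts)
    scale = style["nested_offset_scale"]
    radius = style["nested_circle_radius"]

    rows = []
    for k, inst in enumerate(insts):
        angle = 2 * math.pi * k / m + math.pi / 2
        cd = max(0.0, summ[inst].aggregate_cd)
        rows.append(
            {
                "instrument": inst,
                "angle": angle,
                "offset": radius + scale * cd,
                "radius": radius,
                "aggregate_cd": summ[inst].aggregate_cd,
            }
        )
    inst_df = pd.DataFrame(rows).set_index("instrument", drop=False)

    facet_rows = []
    facet_of_inst: dict[str, list[str]] = {}
    for facet, g in result.item_table.groupby("facet", sort=False):
        inst = g["instrument"].iloc[0]
        facet_of_inst.setdefault(inst, []).append(facet)
    fmax = max((s.aggregate_cd for s in result.facet_summaries.values()), default=0.0)
    for inst, flist in facet_of_inst.items():
        cx = inst_df.loc[inst, "offset"] * math.cos(inst_df.loc[inst, "angle"])
        cy = inst_df.loc[inst, "offset"] * math.sin(inst_df.loc[inst, "angle"])
        for k, facet in enumerate(flist):
            fcd = max(0.0, result.facet_summaries[facet].aggregate_cd)
            r = 0.8 * radius * (fcd / fmax if fmax > 0 else 0.0)
            a = 2 * math.pi * k / len(flist) + math.pi / 2
            facet_rows.append(
                {
                    "facet": facet,
                    "instrument": inst,
                    "x": cx + r * math.cos(a),
                    "y": cy + r * math.sin(a),
                }
            )
    facet_df = pd.DataFrame(facet_rows)

    corr_rows = []
    latent = result.latent_corr
    for i in range(m):
        for j in range(i + 1, m):
            a, b = insts[i], insts[j]
            xa = inst_df.loc[a, "offset"] * math.cos(inst_df.loc[a, "angle"])
            ya = inst_df.loc[a, "offset"] * math.sin(inst_df.loc[a, "angle"])
            xb = inst_df.loc[b, "offset"] * math.cos(inst_df.loc[b, "angle"])
            yb = inst_df.loc[b, "offset"] * math.sin(inst_df.loc[b, "angle"])
            corr_rows.append(
                {
                    "inst_a": a,
                    "inst_b": b,
                    "value": float(latent.loc[a, b]) if a in latent.index and b in latent.columns else np.nan,
                    "x": (xa + xb) / 2,
                    "y": (ya + yb) / 2,
                }
            )
    corr_df = pd.DataFrame(corr_rows)
    return NestedChartLayout(
        instruments=inst_df.reset_index(drop=True),
        facets=facet_df,
        correlations=corr_df,
        title=title,
    )


def _render_item_chart(layout: ItemChartLayout, style: dict):
    fig, ax = plt.subplots(
        figsize=style["figsize"], subplot_kw={"projection": "polar"}
    )
    top = layout.grid_radii[-1] if layout.grid_radii else style["tick_step"]
    for r in layout.grid_radii:
        ax.plot(
            np.linspace(0, 2 * math.pi, 181),
            np.full(181, r),
            ls=":",
            lw=0.6,
            color=style["grid_color"],
        )
    off = style["alternate_offset"] * style["tick_step"]
    for row in layout.items.itertuples():
        ax.plot([row.angle, row.angle], [0, row.radial], color=style["ray_color"], lw=1.2)
        ax.plot([row.angle], [row.radial], marker="o", ms=3, color=style["ray_color"])
        label_r = row.radial + (off if row.alternate else 0.4 * off) + 0.02 * top
        if row.item_id:
            ax.text(
                row.angle, label_r, row.item_id,
                fontsize=style["font_size"], ha="center", va="center",
            )
    for facet, (a0, a1) in layout.facet_sectors.items():
        if facet:
            ax.text(
                (a0 + a1) / 2, top * 1.12, facet,
                fontsize=style["font_size"] + 1, ha="center", va="center", weight="bold",
            )
    ax.set_ylim(0, top * 1.2)
    ax.set_xticks([])
    ax.set_yticks(list(layout.grid_radii))
    ax.set_yticklabels([f"{r:g}" for r in layout.grid_radii], fontsize=style["font_size"] - 1)
    if layout.title:
        ax.set_title(layout.title, fontsize=style["font_size"] + 3)
    return fig


def _render_nested_chart(layout: NestedChartLayout, style: dict):
    fig, ax = plt.subplots(figsize=style["figsize"])
    ax.plot([0], [0], marker="+", ms=10, color=style["grid_color"])
    lim = 0.0
    for row in layout.instruments.itertuples():
        x = row.offset * math.cos(row.angle)
        y = row.offset * math.sin(row.angle)
        circ = plt.Circle(
            (x, y), row.radius, fill=False, color=style["circle_color"], lw=1.4
        )
        ax.add_patch(circ)
        if row.instrument:
            ax.text(
                x, y + row.radius * 1.25, row.instrument,
                fontsize=style["font_size"] + 1, ha="center", va="bottom", weight="bold",
            )
        lim = max(lim, row.offset + 2 * row.radius)
    for row in layout.facets.itertuples():
        ax.plot([row.x], [row.y], marker="o", ms=4, color=style["facet_color"])
        if row.facet:
            ax.text(
                row.x, row.y - 0.015 * max(lim, 1e-9), row.facet,
                fontsize=style["font_size"] - 1, ha="center", va="top",
            )
    for row in layout.correlations.itertuples():
        if not (row.value is None or (isinstance(row.value, float) and math.isnan(row.value))):
            ax.text(
                row.x, row.y, f"{row.value:.2f}",
                fontsize=style["font_size"], ha="center", va="center",
                color=style["grid_color"],
            )
    lim = max(lim * 1.1, 0.1)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.axis("off")
    if layout.title:
        ax.set_title(layout.title, fontsize=style["font_size"] + 3)
    return fig


def render(layout, path, fmt: str = "svg", style: dict | None = None) -> str:
    """Render a layout to SVG (byte-stable for identical input) or PNG."""
    style = {**DEFAULT_STYLE, **(style or {})}
    fmt = fmt.lower()
    if fmt not in ("svg", "png"):
        raise ValueError(f"unsupported format {fmt!r}")
    with matplotlib.rc_context({"svg.hashsalt": style["svg_hashsalt"]}):
        if isinstance(layout, ItemChartLayout):
            fig = _render_item_chart(layout, style)
        elif isinstance(layout, NestedChartLayout):
            fig = _render_nested_chart(layout, style)
        else:
            raise TypeError(f"unknown layout type {type(layout).__name__}")
        try:
            fig.savefig(path, format=fmt, metadata={"Date": None} if fmt == "svg" else None)
        finally:
            plt.close(fig)
    return str(path)
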