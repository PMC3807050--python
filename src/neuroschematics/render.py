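"""SVG realization of the neural-schematic visual grammar.

The grammar is deliberately austere: unfilled black-stroke rectangles for
populations, solid polylines for projections with *no* arrowheads (direction
is fixed by the leave-right/enter-left convention), an empty circle at the
terminus of every inhibitory afferent, dotted horizontal lines with roman
numerals for layers, dotted vertical delimiters with monospace names for
areas and NCRs, and dashed rectangles for functional units.  Colors are
never applied and no glyph is scaled by attribute values; a single stroke
width serves every element class.

Output is SVG 1.1 built with the stdlib XML tree and is byte-identical
across invocations on equal inputs.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass

from neuroschematics.layout import LayoutResult, TextAnchor
from neuroschematics.model import NNSModel, display_label

_SVG_NS = "http://www.w3.org/2000/svg"


class RenderError(ValueError):
    """Layout/model mismatch at render time."""


@dataclass
class StyleConfig:
    """Stroke and typography settings.

    One stroke width for all element classes — the notation forbids
    per-attribute scaling — and no color fields at all: strokes are black,
    fills empty.  Dash patterns are expressed in multiples of the stroke
    width; ``dotted`` is shared by layer and region delimiters, ``dashed``
    marks unit boundaries.
    """

    stroke_width: float = 1.4
    font_family_labels: str = "DejaVu Sans Mono, monospace"
    font_family_population: str = "DejaVu Sans, sans-serif"
    font_size: float = 12.0
    dotted: tuple[float, float] = (1.0, 3.0)
    dashed: tuple[float, float] = (5.0, 3.0)

    def __post_init__(self):
        if self.stroke_width <= 0:
            raise ValueError("stroke width must be strictly positive")

    def dash_value(self, pattern: tuple[float, float]) -> str:
        return f"{_fmt(pattern[0] * self.stroke_width)},{_fmt(pattern[1] * self.stroke_width)}"


def _fmt(v: float) -> str:
    """Stable, compact coordinate formatting."""
    r = round(v, 2)
    return str(int(r)) if r == int(r) else f"{r:g}"


def render_svg(layout: LayoutResult, model: NNSModel, style: StyleConfig | None = None) -> str:
    """Emit an SVG 1.1 document for a computed layout.

    Raises :class:`RenderError` when the layout references identifiers the
    model does not carry (or vice versa).
    """
    style = style or StyleConfig()
    pop_index = {p.id: p for p in model.populations}
    proj_index = {p.id: p for p in model.projections}
    unit_index = {u.id: u for u in model.units}
    for pid in layout.population_boxes:
        if pid not in pop_index:
            raise RenderError(f"layout box for unknown population {pid!r}")
    for pid in layout.projection_paths:
        if pid not in proj_index:
            raise RenderError(f"layout path for unknown projection {pid!r}")
    for pid in pop_index:
        if pid not in layout.population_boxes:
            raise RenderError(f"population {pid!r} missing from layout")

    sw = style.stroke_width
    width, height = layout.canvas.w, layout.canvas.h
    svg = ET.Element(
        "svg",
        {
            "xmlns": _SVG_NS,
            "version": "1.1",
            "width": _fmt(width),
            "height": _fmt(height),
            "viewBox": f"0 0 {_fmt(width)} {_fmt(height)}",
        },
    )
    root = ET.SubElement(svg, "g", {"class": "neural-schematic"})
    stroke = {"stroke": "black", "fill": "none", "stroke-width": _fmt(sw)}

    # hide the single anonymous implicit region (models with layers only)
    regions_visible = not (
        len(model.regions) == 1 and model.regions[0].name == "" and model.regions[0].kind.value == "area"
    )

    # region strips (dotted vertical delimiters + monospace names on top)
    if layout.region_lines and regions_visible:
        g = ET.SubElement(root, "g", {"class": "regions"})
        for x, y0, y1 in layout.region_lines:
            ET.SubElement(
                g,
                "line",
                {
                    "x1": _fmt(x), "y1": _fmt(y0), "x2": _fmt(x), "y2": _fmt(y1),
                    "stroke-dasharray": style.dash_value(style.dotted),
                    **stroke,
                },
            )
        for anchor in layout.region_labels:
            if anchor.text:
                _text(g, anchor, style.font_family_labels, style.font_size, "middle")

    # layer bands (dotted horizontal lines + roman numerals at the right edge)
    if layout.layer_lines:
        g = ET.SubElement(root, "g", {"class": "layers"})
        for line in layout.layer_lines:
            ET.SubElement(
                g,
                "line",
                {
                    "x1": _fmt(line.x_start), "y1": _fmt(line.y),
                    "x2": _fmt(line.x_end), "y2": _fmt(line.y),
                    "stroke-dasharray": style.dash_value(style.dotted),
                    **stroke,
                },
            )
        for anchor in layout.layer_labels:
            _text(g, anchor, style.font_family_labels, style.font_size, "end")

    # units (dashed rectangles, normal-typeset name at the top-left corner)
    if layout.unit_boxes:
        g = ET.SubElement(root, "g", {"class": "units"})
        for uid in sorted(layout.unit_boxes):
            box = layout.unit_boxes[uid]
            unit = unit_index.get(uid)
            if unit is None:
                raise RenderError(f"layout box for unknown unit {uid!r}")
            ET.SubElement(
                g,
                "rect",
                {
                    "x": _fmt(box.x), "y": _fmt(box.y),
                    "width": _fmt(box.w), "height": _fmt(box.h),
                    "stroke-dasharray": style.dash_value(style.dashed),
                    **stroke,
                },
            )
            if unit.name:
                _text(
                    g,
                    TextAnchor(unit.name, box.x + 3, box.y + style.font_size * 0.9),
                    style.font_family_population,
                    style.font_size * 0.8,
                    "start",
                )

    # populations (solid unfilled rectangles + two-part styled labels)
    if layout.population_boxes:
        g = ET.SubElement(root, "g", {"class": "populations"})
    for pid in sorted(layout.population_boxes):
        box = layout.population_boxes[pid]
        pop = pop_index[pid]
        ET.SubElement(
            g,
            "rect",
            {
                "x": _fmt(box.x), "y": _fmt(box.y),
                "width": _fmt(box.w), "height": _fmt(box.h),
                **stroke,
            },
        )
        text = ET.SubElement(
            g,
            "text",
            {
                "x": _fmt(box.cx),
                "y": _fmt(box.cy + style.font_size * 0.35),
                "text-anchor": "middle",
                "font-family": style.font_family_population,
                "font-size": _fmt(style.font_size),
                "fill": "black",
            },
        )
        for span, span_style in display_label(pop.label):
            tspan = ET.SubElement(text, "tspan")
            if span_style == "italic":
                tspan.set("font-style", "italic")
            tspan.text = span

    # projections (solid polylines, no arrowheads; empty circle marks an
    # inhibitory terminus; density labels at the path midpoint)
    if layout.projection_paths:
        g = ET.SubElement(root, "g", {"class": "projections"})
    for pid in sorted(layout.projection_paths):
        path = layout.projection_paths[pid]
        pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in path.points)
        ET.SubElement(g, "polyline", {"points": pts, **stroke})
        if path.inhibitory:
            (xe, ye) = path.points[-1]
            r = _terminator_radius(style)
            ET.SubElement(
                g,
                "circle",
                {
                    "cx": _fmt(xe - r), "cy": _fmt(ye), "r": _fmt(r),
                    "class": "inhibitory-terminator",
                    **stroke,
                },
            )
        if path.density is not None:
            mx, my = _midpoint(path.points)
            _text(
                g,
                TextAnchor(_fmt_density(path.density), mx, my - 3),
                style.font_family_population,
                style.font_size * 0.8,
                "middle",
            )

    body = ET.tostring(svg, encoding="unicode")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + body + "\n"


def _terminator_radius(style: StyleConfig) -> float:
    # the notation fixes the terminator as an *empty* circle but not its
    # size; three stroke widths reads well at print scale
    return 3.0 * style.stroke_width


def _midpoint(points: tuple[tuple[float, float], ...]) -> tuple[float, float]:
    seg = (len(points) - 1) // 2
    (x1, y1), (x2, y2) = points[seg], points[seg + 1]
    return (x1 + x2) / 2, (y1 + y2) / 2


def _fmt_density(d: float) -> str:
    return f"{d:g}"


def _text(parent, anchor: TextAnchor, family: str, size: float, text_anchor: str):
    el = ET.SubElement(
        parent,
        "text",
        {
            "x": _fmt(anchor.x),
            "y": _fmt(anchor.y),
            "text-anchor": text_anchor,
            "font-family": family,
            "font-size": _fmt(size),
            "fill": "black",
        },
    )
    el.text = anchor.text
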