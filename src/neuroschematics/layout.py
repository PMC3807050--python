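"""Deterministic automatic layout for neural schematics.

The notation fixes topology conventions, not metrics: projections leave a
population rectangle on its right edge and enter on the left edge, layer
bands stack with the highest cortical layer (smallest numeral) on top, and
regions (areas and NCRs) occupy vertical strips ordered by display order.
The placement algorithm realizing those constraints works on a grid
scaffold:

* columns — one vertical strip per region in display order, plus a trailing
  implicit strip for populations without a region;
* rows — one horizontal band per distinct layer numeral in use, top-to-bottom
  by increasing numeral, plus a trailing band for layer-less populations;
* within a cell — populations grouped by unit-membership chain (so dashed
  unit boxes never swallow non-members), ordered inside a group by
  longest-path rank over the cell-internal projection graph (source-to-sink
  flow matching the left-in/right-out convention), ties by identifier.

Routing is orthogonal (Manhattan) with greedy channel-track allocation in
projection-id order; self-loops are carried over the top of their box.  The
whole computation is a pure function of (model, config): equal inputs give
equal geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from neuroschematics.model import EXTERNAL, NNSModel, display_label
from neuroschematics.validation import validate_model

_NOLAYER = 10 ** 6  # sorts after every real layer numeral
_NOREGION = "￿__noregion__"  # sorts after every real region id


class LayoutError(ValueError):
    """Raised for infeasible layout configurations."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle (x, y = top-left corner; y grows downward)."""

    x: float
    y: float
    w: float
    h: float

    @property
    def right(self) -> float:
        return self.x + self.w

    @property
    def bottom(self) -> float:
        return self.y + self.h

    @property
    def cx(self) -> float:
        return self.x + self.w / 2

    @property
    def cy(self) -> float:
        return self.y + self.h / 2

    def contains(self, other: "Rect", margin: float = 0.0) -> bool:
        return (
            other.x >= self.x + margin - 1e-9
            and other.y >= self.y + margin - 1e-9
            and other.right <= self.right - margin + 1e-9
            and other.bottom <= self.bottom - margin + 1e-9
        )

    def intersects(self, other: "Rect") -> bool:
        return not (
            other.x >= self.right
            or other.right <= self.x
            or other.y >= self.bottom
            or other.bottom <= self.y
        )


@dataclass
class LayoutConfig:
    """Metric knobs of the layout, in abstract length units (rendered 1:1 as
    SVG user units).  All lengths must be strictly positive."""

    box_min_size: tuple[float, float] = (64.0, 32.0)
    band_gap: float = 22.0
    column_gap: float = 48.0
    channel_spacing: float = 8.0
    unit_margin: float = 10.0
    loop_margin: float = 12.0
    terminator_radius: float = 4.5
    font_size: float = 12.0
    margin: float = 46.0  # canvas margin hosting input/output stubs and labels

    def __post_init__(self):
        lengths = {
            "box_min_size.w": self.box_min_size[0],
            "box_min_size.h": self.box_min_size[1],
            "band_gap": self.band_gap,
            "column_gap": self.column_gap,
            "channel_spacing": self.channel_spacing,
            "unit_margin": self.unit_margin,
            "loop_margin": self.loop_margin,
            "terminator_radius": self.terminator_radius,
            "font_size": self.font_size,
            "margin": self.margin,
        }
        for name, value in lengths.items():
            if value <= 0:
                raise LayoutError(f"layout length {name} must be strictly positive, got {value}")
        if self.band_gap <= self.loop_margin:
            raise LayoutError(
                "band_gap must exceed loop_margin so self-loops stay inside their band"
            )


@dataclass(frozen=True)
class Path:
    """Orthogonal polyline for a projection, plus its terminator flag."""

    points: tuple[tuple[float, float], ...]
    inhibitory: bool
    density: Optional[float]


@dataclass(frozen=True)
class LayerLine:
    y: float
    x_start: float
    x_end: float


@dataclass(frozen=True)
class TextAnchor:
    text: str
    x: float
    y: float


@dataclass
class LayoutResult:
    """Resolved geometry for one schematic."""

    population_boxes: dict[str, Rect] = field(default_factory=dict)
    projection_paths: dict[str, Path] = field(default_factory=dict)
    layer_lines: list[LayerLine] = field(default_factory=list)
    layer_labels: list[TextAnchor] = field(default_factory=list)
    region_lines: list[tuple[float, float, float]] = field(default_factory=list)  # x, y0, y1
    region_labels: list[TextAnchor] = field(default_factory=list)
    unit_boxes: dict[str, Rect] = field(default_factory=dict)
    canvas: Rect = Rect(0, 0, 0, 0)
    warnings: list[str] = field(default_factory=list)


def _label_width(model_pop, config: LayoutConfig) -> float:
    # text metrics via character-count heuristic: no font files needed
    text = "".join(t for t, _ in display_label(model_pop.label))
    return max(config.box_min_size[0], len(text) * config.font_size * 0.62 + 18)


def _unit_chain(model: NNSModel, pid: str) -> tuple[str, ...]:
    """Unit-membership chain of a population from root unit downward."""
    owner = {m: u.id for u in model.units for m in u.members}
    chain: list[str] = []
    node = pid
    seen = set()
    while node in owner and node not in seen:
        seen.add(node)
        chain.append(owner[node])
        node = owner[node]
    return tuple(reversed(chain))


def compute_layout(model: NNSModel, config: LayoutConfig | None = None) -> LayoutResult:
    """Place and route a validated model; pure function of its inputs."""
    config = config or LayoutConfig()
    errors = [d for d in validate_model(model) if d.severity == "ERROR"]
    if errors:
        raise LayoutError(f"cannot lay out a model with rule errors: {errors[0]}")

    result = LayoutResult()
    if model.is_empty():
        return result

    box_w = {p.id: _label_width(p, config) for p in model.populations}
    box_h = config.box_min_size[1]

    # -- grid scaffold ---------------------------------------------------
    region_cols = [r.id for r in model.regions]
    has_unplaced = any(p.region_ref is None for p in model.populations)
    columns = region_cols + ([_NOREGION] if has_unplaced or not region_cols else [])
    if not columns:
        columns = [_NOREGION]

    layer_values = sorted({l.order_index for l in model.layers})
    rows = layer_values + [_NOLAYER] if layer_values else [_NOLAYER]
    layer_of_pop: dict[str, int] = {}
    for p in model.populations:
        if p.layer_ref is not None:
            layer = next(
                l for l in model.layers if l.area_ref == p.region_ref and l.name == p.layer_ref
            )
            layer_of_pop[p.id] = layer.order_index
        else:
            layer_of_pop[p.id] = _NOLAYER

    cells: dict[tuple[int, str], list[str]] = {}
    for p in model.populations:
        col = p.region_ref if p.region_ref is not None else _NOREGION
        cells.setdefault((layer_of_pop[p.id], col), []).append(p.id)

    # -- within-cell ordering ---------------------------------------------
    chains = {p.id: _unit_chain(model, p.id) for p in model.populations}
    internal = [pr for pr in model.projections if not pr.is_input and not pr.is_output]
    rank_of: dict[str, int] = {}
    for cell_pops in cells.values():
        cell_set = set(cell_pops)
        g = nx.DiGraph()
        g.add_nodes_from(sorted(cell_set))
        for pr in internal:
            if pr.source in cell_set and pr.target in cell_set and pr.source != pr.target:
                g.add_edge(pr.source, pr.target)
        # longest-path rank over the condensation (cycles collapse to one rank)
        cond = nx.condensation(g)
        comp_rank = {n: 0 for n in nx.topological_sort(cond)}
        for n in nx.topological_sort(cond):
            for succ in cond.successors(n):
                comp_rank[succ] = max(comp_rank[succ], comp_rank[n] + 1)
        for comp, rank in comp_rank.items():
            for pid in cond.nodes[comp]["members"]:
                rank_of[pid] = rank
    def group_key(pid: str):
        # a population sitting directly in a parent unit sorts after its
        # sibling sub-units, keeping nested dashed boxes contiguous
        return chains[pid] + ("￿",)

    for key in cells:
        cells[key].sort(key=lambda pid: (group_key(pid), rank_of.get(pid, 0), pid))

    # -- cell extents -----------------------------------------------------
    intra_gap = config.channel_spacing * 3
    cell_pad = config.unit_margin + config.channel_spacing

    def cell_width(pops: list[str]) -> float:
        if not pops:
            return 0.0
        width = sum(box_w[p] for p in pops) + intra_gap * (len(pops) - 1)
        # extra room where unit membership changes between neighbours,
        # so unit borders have clearance
        for a, b in zip(pops, pops[1:]):
            if chains[a] != chains[b]:
                width += 2 * config.unit_margin + config.channel_spacing
        return width + 2 * cell_pad

    col_width = {
        col: max(
            [cell_width(cells.get((row, col), [])) for row in rows]
            + [config.box_min_size[0] + 2 * cell_pad]
        )
        for col in columns
    }
    band_height = box_h + 2 * config.band_gap

    # -- coordinates ------------------------------------------------------
    x0 = config.margin
    top = config.margin
    col_x: dict[str, float] = {}
    x = x0
    for col in columns:
        col_x[col] = x
        x += col_width[col] + config.column_gap
    content_right = x - config.column_gap

    row_y = {row: top + i * band_height for i, row in enumerate(rows)}
    content_bottom = top + len(rows) * band_height

    for (row, col), pops in sorted(cells.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        cx = col_x[col] + cell_pad
        cy = row_y[row] + config.band_gap
        for i, pid in enumerate(pops):
            if i > 0 and chains[pops[i - 1]] != chains[pid]:
                cx += 2 * config.unit_margin + config.channel_spacing
            result.population_boxes[pid] = Rect(cx, cy, box_w[pid], box_h)
            cx += box_w[pid] + intra_gap

    # -- unit boxes (children before parents) ------------------------------
    unit_ids = {u.id for u in model.units}
    depth: dict[str, int] = {}

    def unit_depth(uid: str, trail=()) -> int:
        if uid in depth:
            return depth[uid]
        kids = [m for m in model.unit(uid).members if m in unit_ids and m not in trail]
        depth[uid] = 1 + max((unit_depth(k, trail + (uid,)) for k in kids), default=0)
        return depth[uid]

    for u in sorted(model.units, key=lambda u: (unit_depth(u.id), u.id)):
        boxes = []
        for m in u.members:
            if m in result.population_boxes:
                boxes.append(result.population_boxes[m])
            elif m in result.unit_boxes:
                boxes.append(result.unit_boxes[m])
        if boxes:
            xa = min(b.x for b in boxes) - config.unit_margin
            ya = min(b.y for b in boxes) - config.unit_margin
            xb = max(b.right for b in boxes) + config.unit_margin
            yb = max(b.bottom for b in boxes) + config.unit_margin
            result.unit_boxes[u.id] = Rect(xa, ya, xb - xa, yb - ya)
        else:
            # an empty unit still gets a visible dashed box below the content
            side = config.box_min_size[0] / 2
            offset = len(result.unit_boxes) * (side + config.channel_spacing)
            result.unit_boxes[u.id] = Rect(x0 + offset, content_bottom, side, side)
            result.warnings.append(f"unit {u.id} has no placeable members")

    # warn on genuine interleaving of non-nested unit boxes
    nested: set[tuple[str, str]] = set()
    for u in model.units:
        stack = [m for m in u.members if m in unit_ids]
        while stack:
            k = stack.pop()
            nested.add((u.id, k))
            nested.add((k, u.id))
            stack.extend(m for m in model.unit(k).members if m in unit_ids)
    uids = sorted(result.unit_boxes)
    for i, a in enumerate(uids):
        for b in uids[i + 1 :]:
            if (a, b) not in nested and result.unit_boxes[a].intersects(result.unit_boxes[b]):
                result.warnings.append(f"unit boxes {a} and {b} interleave and overlap")

    # -- attachment points --------------------------------------------------
    incoming: dict[str, list[str]] = {}
    outgoing: dict[str, list[str]] = {}
    for pr in model.projections:  # already sorted by id
        if pr.target != EXTERNAL:
            incoming.setdefault(pr.target, []).append(pr.id)
        if pr.source != EXTERNAL:
            outgoing.setdefault(pr.source, []).append(pr.id)

    def attach_y(box: Rect, ids: list[str], pid: str) -> float:
        i = ids.index(pid)
        return box.y + box.h * (i + 1) / (len(ids) + 1)

    # -- routing -----------------------------------------------------------
    track_count: dict[tuple[str, float], int] = {}

    def take_track(key: tuple[str, float]) -> int:
        n = track_count.get(key, 0)
        track_count[key] = n + 1
        return n

    canvas_left = 0.0
    canvas_right = content_right + config.margin
    cs = config.channel_spacing

    for pr in model.projections:
        density = pr.density
        inhib = pr.excitation.value == "inhibitory"
        if pr.is_input:
            tbox = result.population_boxes[pr.target]
            ty = attach_y(tbox, incoming[pr.target], pr.id)
            pts = ((canvas_left, ty), (tbox.x, ty))
        elif pr.is_output:
            sbox = result.population_boxes[pr.source]
            sy = attach_y(sbox, outgoing[pr.source], pr.id)
            pts = ((sbox.right, sy), (canvas_right, sy))
        elif pr.is_self_loop:
            box = result.population_boxes[pr.source]
            sy = attach_y(box, outgoing[pr.source], pr.id)
            ty = attach_y(box, incoming[pr.source], pr.id)
            n = take_track(("loop", box.x))
            rise = config.loop_margin + n * 3
            pts = (
                (box.right, sy),
                (box.right + cs + n * 3, sy),
                (box.right + cs + n * 3, box.y - rise),
                (box.x - cs - n * 3, box.y - rise),
                (box.x - cs - n * 3, ty),
                (box.x, ty),
            )
        else:
            sbox = result.population_boxes[pr.source]
            tbox = result.population_boxes[pr.target]
            sy = attach_y(sbox, outgoing[pr.source], pr.id)
            ty = attach_y(tbox, incoming[pr.target], pr.id)
            if sbox.right + 2 * cs <= tbox.x:
                # forward route through the channel left of the target
                n = take_track(("fwd", tbox.x))
                mx = max(sbox.right + cs / 2, tbox.x - cs * (1 + n % 4) - (n // 4) * 2)
                if abs(sy - ty) < 1e-9:
                    pts = ((sbox.right, sy), (tbox.x, ty))
                else:
                    pts = ((sbox.right, sy), (mx, sy), (mx, ty), (tbox.x, ty))
            else:
                # backward or overlapping: detour below both boxes
                n = take_track(("back", tbox.x))
                out_x = sbox.right + cs * (1 + n % 3) + (n // 3) * 2
                in_x = tbox.x - cs * (1 + n % 3) - (n // 3) * 2
                dy = max(sbox.bottom, tbox.bottom) + config.loop_margin + n * 3
                pts = (
                    (sbox.right, sy),
                    (out_x, sy),
                    (out_x, dy),
                    (in_x, dy),
                    (in_x, ty),
                    (tbox.x, ty),
                )
        result.projection_paths[pr.id] = Path(points=pts, inhibitory=inhib, density=density)

    # -- layer lines and labels ---------------------------------------------
    drawn_label_rows: set[int] = set()
    for region in model.regions:
        area_layers = model.layers_of(region.id)
        if not area_layers:
            continue
        xs, xe = col_x[region.id], col_x[region.id] + col_width[region.id]
        for layer in area_layers:
            y_top = row_y[layer.order_index]
            result.layer_lines.append(LayerLine(y=y_top, x_start=xs, x_end=xe))
            result.layer_lines.append(
                LayerLine(y=y_top + band_height, x_start=xs, x_end=xe)
            )
            if layer.order_index not in drawn_label_rows:
                drawn_label_rows.add(layer.order_index)
                result.layer_labels.append(
                    TextAnchor(
                        text=layer.name,
                        x=canvas_right - 4,
                        y=row_y[layer.order_index] + band_height / 2,
                    )
                )
    # dedupe coincident lines
    result.layer_lines = sorted(
        set(result.layer_lines), key=lambda l: (l.y, l.x_start, l.x_end)
    )
    result.layer_labels.sort(key=lambda a: a.y)

    # -- region strips ---------------------------------------------------
    region_y0, region_y1 = top - config.band_gap, content_bottom + config.band_gap / 2
    for region in model.regions:
        xs, xe = col_x[region.id], col_x[region.id] + col_width[region.id]
        result.region_lines.append((xs, region_y0, region_y1))
        result.region_lines.append((xe, region_y0, region_y1))
        result.region_labels.append(
            TextAnchor(text=region.name, x=(xs + xe) / 2, y=region_y0 - 6)
        )
    result.region_lines = sorted(set(result.region_lines))

    # -- canvas ------------------------------------------------------------
    ys = [content_bottom]
    for path in result.projection_paths.values():
        ys.extend(y for _, y in path.points)
    for box in result.unit_boxes.values():
        ys.append(box.bottom)
    height = max(ys) + config.margin
    result.canvas = Rect(0, 0, canvas_right + config.margin / 2, height)
    return result
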