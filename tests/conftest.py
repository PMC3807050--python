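"""Shared fixtures and geometric/SVG oracles for the test suite."""

from __future__ import annotations

import xml.etree.ElementTree as ET

import pytest
from hypothesis import settings

from neuroschematics import FixtureId, build_fixture, compute_layout, render_svg

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

SVG_NS = {"svg": "http://www.w3.org/2000/svg"}


@pytest.fixture(params=list(FixtureId), ids=lambda f: f.value)
def fixture_model(request):
    """Each built-in example schematic in turn."""
    return build_fixture(request.param)


@pytest.fixture
def fig8():
    return build_fixture(FixtureId.FIG8_PROJECTIONS)


@pytest.fixture
def fig11():
    return build_fixture(FixtureId.FIG11_SYNFIRE_FFI)


@pytest.fixture
def fig12():
    return build_fixture(FixtureId.FIG12_HYPERCOLUMN)


def svg_root(model, style=None) -> ET.Element:
    layout = compute_layout(model)
    return ET.fromstring(render_svg(layout, model, style))


# ---------------------------------------------------------------------------
# independent geometric predicates (brute force, no layout internals)
# ---------------------------------------------------------------------------

def boxes_overlap(a, b) -> bool:
    return not (
        a.x + a.w <= b.x or b.x + b.w <= a.x or a.y + a.h <= b.y or b.y + b.h <= a.y
    )


def count_box_overlaps(layout) -> int:
    boxes = [layout.population_boxes[k] for k in sorted(layout.population_boxes)]
    return sum(
        1 for i in range(len(boxes)) for j in range(i + 1, len(boxes))
        if boxes_overlap(boxes[i], boxes[j])
    )


def on_left_edge(point, box, tol=1e-9) -> bool:
    x, y = point
    return abs(x - box.x) <= tol and box.y - tol <= y <= box.y + box.h + tol


def on_right_edge(point, box, tol=1e-9) -> bool:
    x, y = point
    return abs(x - (box.x + box.w)) <= tol and box.y - tol <= y <= box.y + box.h + tol


def endpoint_sides_ok(model, layout) -> bool:
    """Every projection leaves on the right edge and enters on the left edge
    (self-loops right-out/left-in; externals start/end at the canvas edge)."""
    for proj in model.projections:
        path = layout.projection_paths[proj.id].points
        if proj.source != "EXTERNAL":
            if not on_right_edge(path[0], layout.population_boxes[proj.source]):
                return False
        else:
            if path[0][0] != layout.canvas.x:
                return False
        if proj.target != "EXTERNAL":
            if not on_left_edge(path[-1], layout.population_boxes[proj.target]):
                return False
        else:
            # outputs run to the right canvas margin, past every box
            rightmost = max(b.x + b.w for b in layout.population_boxes.values())
            if path[-1][0] < rightmost:
                return False
    return True
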