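"""SVG grammar introspection: strokes, terminators, dashes, typography."""

import xml.etree.ElementTree as ET

import pytest

from neuroschematics import (
    NNSModel,
    StyleConfig,
    compute_layout,
    render_svg,
)
from neuroschematics.fixtures import build_fixture
from neuroschematics.render import RenderError

from conftest import SVG_NS, svg_root


def _tag(el):
    return el.tag.split("}")[-1]


class TestVisualGrammar:
    def test_one_unfilled_rect_per_population(self, fixture_model):
        root = svg_root(fixture_model)
        pops = root.find(".//svg:g[@class='populations']", SVG_NS)
        rects = pops.findall("svg:rect", SVG_NS) if pops is not None else []
        assert len(rects) == len(fixture_model.populations)
        for rect in rects:
            assert rect.get("fill") == "none"
            assert rect.get("stroke-dasharray") is None  # population strokes are solid

    def test_no_arrowheads_anywhere(self, fixture_model):
        root = svg_root(fixture_model)
        assert not [el for el in root.iter() if el.get("marker-end") or el.get("marker-start")]
        assert not root.findall(".//svg:marker", SVG_NS)

    def test_no_colors_other_than_black(self, fixture_model):
        for el in svg_root(fixture_model).iter():
            for attr in ("stroke", "fill", "color"):
                assert el.get(attr) in (None, "black", "none")

    def test_terminator_circles_equal_inhibitory_count(self, fixture_model):
        """An empty circle marks each inhibitory terminus and nothing else,
        cross-checked by scanning the model."""
        circles = svg_root(fixture_model).findall(".//svg:circle", SVG_NS)
        inhibitory = sum(
            1 for p in fixture_model.projections if p.excitation.value == "inhibitory"
        )
        assert len(circles) == inhibitory
        for c in circles:
            assert c.get("fill") == "none"

    def test_fig8_single_terminator_four_polylines(self, fig8):
        root = svg_root(fig8)
        assert len(root.findall(".//svg:circle", SVG_NS)) == 1
        assert len(root.findall(".//svg:polyline", SVG_NS)) == 4

    def test_dash_patterns_exactly_on_layer_region_unit_strokes(self, fixture_model):
        root = svg_root(fixture_model)
        main = root.find("svg:g", SVG_NS)
        for group in main.findall("svg:g", SVG_NS):
            should_dash = group.get("class") in ("layers", "regions", "units")
            for el in group.iter():
                if _tag(el) in ("line", "rect", "polyline", "circle"):
                    dashed = el.get("stroke-dasharray") is not None
                    assert dashed == should_dash, ET.tostring(el)

    def test_italic_spans_exactly_on_morph_tokens(self, fixture_model):
        root = svg_root(fixture_model)
        italic = [
            t.text for t in root.findall(".//svg:tspan", SVG_NS)
            if t.get("font-style") == "italic"
        ]
        normal = [
            t.text for t in root.findall(".//svg:tspan", SVG_NS)
            if t.get("font-style") is None
        ]
        expected_italic = sorted(
            p.label.morph_class for p in fixture_model.populations if p.label.morph_class
        )
        expected_normal = sorted(
            [p.label.electrophys_class for p in fixture_model.populations
             if p.label.electrophys_class]
            + ["/" for p in fixture_model.populations
               if p.label.electrophys_class and p.label.morph_class]
        )
        assert sorted(italic) == expected_italic
        assert sorted(normal) == expected_normal

    def test_fig11_three_dashed_unit_rects(self, fig11):
        root = svg_root(fig11)
        units = root.find(".//svg:g[@class='units']", SVG_NS)
        assert len(units.findall("svg:rect", SVG_NS)) == 3

    def test_density_labels_printed_verbatim(self, fig8):
        texts = {t.text for t in svg_root(fig8).findall(".//svg:text", SVG_NS)}
        assert {"0.5", "0.1", "0.2"} <= texts

    def test_layer_labels_monospace_roman(self):
        root = svg_root(build_fixture("FIG10_THALAMOCORTICAL"))
        layers = root.find(".//svg:g[@class='layers']", SVG_NS)
        labels = layers.findall("svg:text", SVG_NS)
        assert [t.text for t in labels] == ["VI"]
        assert "mono" in labels[0].get("font-family")

    def test_fig12_region_delimiters_suppressed_for_anonymous_area(self, fig12):
        """Layer-only schematics show no vertical region lines."""
        root = svg_root(fig12)
        assert root.find(".//svg:g[@class='regions']", SVG_NS) is None
        assert root.find(".//svg:g[@class='layers']", SVG_NS) is not None


class TestDocument:
    def test_byte_determinism(self, fixture_model):
        a = render_svg(compute_layout(fixture_model), fixture_model)
        b = render_svg(compute_layout(fixture_model), fixture_model)
        assert a.encode() == b.encode()

    def test_valid_svg_11(self, fixture_model):
        root = svg_root(fixture_model)
        assert root.tag == "{http://www.w3.org/2000/svg}svg"
        assert root.get("version") == "1.1"
        assert root.get("viewBox")

    def test_empty_model_valid_document(self):
        model = NNSModel()
        text = render_svg(compute_layout(model), model)
        root = ET.fromstring(text)
        group = root.find("svg:g", SVG_NS)
        assert group is not None and len(list(group)) == 0

    def test_layout_model_mismatch_raises(self, fig8, fig11):
        layout = compute_layout(fig11)
        with pytest.raises(RenderError):
            render_svg(layout, fig8)

    def test_single_stroke_width_for_all_elements(self, fixture_model):
        widths = {
            el.get("stroke-width")
            for el in svg_root(fixture_model).iter()
            if el.get("stroke-width")
        }
        assert len(widths) == 1

    def test_style_rejects_nonpositive_stroke(self):
        with pytest.raises(ValueError):
            StyleConfig(stroke_width=0)
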