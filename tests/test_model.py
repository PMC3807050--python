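"""Core model types: labels, endpoint classification, construction invariants."""

import pytest
from hypothesis import given, strategies as st

from neuroschematics import (
    EXTERNAL,
    ExcitationType,
    InvalidElementError,
    Layer,
    ModelValidationError,
    NNSModel,
    Population,
    PopulationLabel,
    Projection,
    Region,
    RegionKind,
    Unit,
    classify_endpoints,
    display_label,
)
from neuroschematics.fixtures import build_fixture, random_model

TOKEN = st.from_regex(r"^[A-Z0-9]{1,6}$")


class TestDisplayLabel:
    @pytest.mark.parametrize(
        "electro, morph, expected",
        [
            ("RS", "PYR", [("RS", "normal"), ("/", "normal"), ("PYR", "italic")]),
            (None, "TC", [("TC", "italic")]),
            (None, "RE", [("RE", "italic")]),
            ("POIS", None, [("POIS", "normal")]),
            ("FS", "NPYR", [("FS", "normal"), ("/", "normal"), ("NPYR", "italic")]),
        ],
    )
    def test_styled_spans(self, electro, morph, expected):
        """The electrophysiological class renders normal, the morphological
        or other descriptive class renders italic, joined by a slash."""
        assert display_label(PopulationLabel(electro, morph)) == expected

    def test_empty_label_rejected(self):
        with pytest.raises(InvalidElementError):
            PopulationLabel(None, None)

    @pytest.mark.parametrize("bad", ["rs", "R S", "pyr!", ""])
    def test_malformed_tokens_rejected(self, bad):
        with pytest.raises(InvalidElementError):
            PopulationLabel(electrophys_class=bad)

    @given(
        a=st.tuples(TOKEN, TOKEN),
        b=st.tuples(TOKEN, TOKEN),
    )
    def test_injective_on_distinct_pairs(self, a, b):
        """Distinct (electrophys, morph) pairs give distinct span lists."""
        la, lb = PopulationLabel(*a), PopulationLabel(*b)
        if a != b:
            assert display_label(la) != display_label(lb)
        else:
            assert display_label(la) == display_label(lb)


class TestClassifyEndpoints:
    def test_empty_model(self):
        parts = classify_endpoints(NNSModel())
        assert parts == {"internal": set(), "inputs": set(), "outputs": set()}

    def test_fig10_stimulus_afferents_are_inputs(self):
        model = build_fixture("FIG10_THALAMOCORTICAL")
        parts = classify_endpoints(model)
        external_sources = {p.id for p in model.projections if p.source == EXTERNAL}
        assert external_sources and parts["inputs"] == external_sources

    def test_matches_brute_force_scan(self):
        model = random_model(seed=1, n_pop=12, n_proj=30, p_external=0.2)
        parts = classify_endpoints(model)
        # independent scan of every projection's endpoints
        expected = {"internal": set(), "inputs": set(), "outputs": set()}
        for proj in model.projections:
            if proj.source == EXTERNAL:
                expected["inputs"].add(proj.id)
            elif proj.target == EXTERNAL:
                expected["outputs"].add(proj.id)
            else:
                expected["internal"].add(proj.id)
        assert parts == expected

    @given(seed=st.integers(0, 10_000))
    def test_partition_covers_all_projections(self, seed):
        model = random_model(seed=seed, n_pop=5, n_proj=12, p_external=0.3)
        parts = classify_endpoints(model)
        sizes = sum(len(s) for s in parts.values())
        assert sizes == len(model.projections)
        assert not (parts["inputs"] & parts["outputs"] & parts["internal"])


class TestConstructionInvariants:
    def test_projection_both_external_rejected(self):
        with pytest.raises(InvalidElementError):
            Projection("p", EXTERNAL, EXTERNAL, ExcitationType.EXCITATORY)

    def test_self_projection_permitted(self):
        proj = Projection("p", "a", "a", ExcitationType.EXCITATORY)
        assert proj.is_self_loop

    @pytest.mark.parametrize("density", [-0.1, 1.5])
    def test_density_bounds(self, density):
        with pytest.raises(InvalidElementError):
            Projection("p", "a", "b", ExcitationType.EXCITATORY, density=density)

    @pytest.mark.parametrize("name", ["VII", "iv", "1", "X"])
    def test_layer_names_restricted_to_roman_i_vi(self, name):
        with pytest.raises(InvalidElementError):
            Layer(name, "area")

    def test_layer_order_index_derived_from_numeral(self):
        assert Layer("IV", "a").order_index == 4
        with pytest.raises(InvalidElementError):
            Layer("IV", "a", order_index=2)

    def test_strict_model_construction_rejects_dangling_refs(self):
        with pytest.raises(ModelValidationError):
            NNSModel(
                projections=[Projection("p", "ghost", EXTERNAL, ExcitationType.EXCITATORY)]
            )

    def test_layered_population_requires_containing_area(self):
        """A population with a layer must live in an area housing that layer,
        never in an NCR."""
        with pytest.raises(ModelValidationError):
            NNSModel(
                regions=[Region("ncr", RegionKind.NCR, "Thalamus")],
                populations=[
                    Population(
                        "p", PopulationLabel("RS", "PYR"), layer_ref="I", region_ref="ncr"
                    )
                ],
            )

    def test_unit_membership_sorted_and_duplicate_free(self):
        unit = Unit("u", "column", members=["b", "a"])
        assert unit.members == ["a", "b"]
        with pytest.raises(InvalidElementError):
            Unit("u", "column", members=["a", "a"])

    def test_extra_attributes_do_not_affect_geometry(self):
        from neuroschematics import compute_layout

        plain = build_fixture("FIG8_PROJECTIONS")
        decorated = build_fixture("FIG8_PROJECTIONS")
        decorated.populations[0].extra_attributes["neuron_model"] = "IF_cond_exp"
        decorated.projections[0].extra_attributes["weight"] = 5.0
        la, lb = compute_layout(plain), compute_layout(decorated)
        assert la.population_boxes == lb.population_boxes
        assert la.projection_paths == lb.projection_paths
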