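"""Rulebook validator: single-fault injection with per-rule brute-force
oracles, clean-fixture conformance, diagnostic ordering."""

import copy

import pytest

from neuroschematics import (
    EXTERNAL,
    Layer,
    NNSModel,
    Population,
    PopulationLabel,
    Region,
    RegionKind,
    validate_model,
)
from neuroschematics.fixtures import random_model
from neuroschematics.model import _ROMAN_VALUES, _TOKEN_RE
from neuroschematics.validation import RULE_IDS, format_diagnostics


def base_model(seed: int) -> NNSModel:
    """A clean random model guaranteed to contain an area with layers, an
    NCR, units with members, and internal plus external projections."""
    r = random_model(
        seed=seed, n_pop=6, n_proj=10, n_layers=2, n_regions=2, n_units=2,
        p_inhibitory=0.3, p_external=0.2,
    )
    pops = r.populations + [
        Population("zz_ncr_pop", PopulationLabel("RS", "PYR"), region_ref="zz_ncr")
    ]
    regions = r.regions + [Region("zz_ncr", RegionKind.NCR, "NCR", display_order=99)]
    return NNSModel(
        populations=pops, projections=r.projections, layers=r.layers,
        regions=regions, units=r.units,
    )


# ---------------------------------------------------------------------------
# fault injectors: mutate a clean model to violate exactly one rule
# ---------------------------------------------------------------------------

def _inject_pop_label(m):
    m.populations[0].label.electrophys_class = None
    m.populations[0].label.morph_class = None


def _inject_proj_endpoints(m):
    m.projections[0].source = EXTERNAL
    m.projections[0].target = EXTERNAL


def _inject_proj_density(m):
    m.projections[0].density = 1.7


def _inject_layer_name(m):
    # fresh layer with a non-roman name; existing layer refs stay intact
    bad = Layer("V", m.layers[0].area_ref)
    bad.name = "VII"
    m.layers.append(bad)


def _inject_layer_order(m):
    m.layers[0].order_index = m.layers[0].order_index + 1


def _inject_ncr_nolayers(m):
    m.layers.append(Layer("VI", "zz_ncr"))


def _inject_unit_forest(m):
    # a population directly member of two units
    donor = next(p for p in m.units[1].members if not p.startswith("u"))
    m.units[0].members.append(donor)


def _inject_ref_integrity(m):
    m.projections[0].target = "no_such_population"


def _inject_no_color(m):
    m.populations[0].extra_attributes["fill_color"] = "red"


def _inject_no_scaling(m):
    m.projections[0].extra_attributes["scale_by"] = "density"


INJECTORS = {
    "R-POP-LABEL": _inject_pop_label,
    "R-PROJ-ENDPOINTS": _inject_proj_endpoints,
    "R-PROJ-DENSITY": _inject_proj_density,
    "R-LAYER-NAME": _inject_layer_name,
    "R-LAYER-ORDER": _inject_layer_order,
    "R-NCR-NOLAYERS": _inject_ncr_nolayers,
    "R-UNIT-FOREST": _inject_unit_forest,
    "R-REF-INTEGRITY": _inject_ref_integrity,
    "R-NO-COLOR": _inject_no_color,
    "R-NO-SCALING": _inject_no_scaling,
}


# per-rule brute-force oracles: independent, naive re-scans of the model
def _oracle(rule: str, m: NNSModel) -> bool:
    if rule == "R-POP-LABEL":
        return any(
            (not p.label.electrophys_class and not p.label.morph_class)
            or any(
                t is not None and not _TOKEN_RE.match(t)
                for t in (p.label.electrophys_class, p.label.morph_class)
            )
            for p in m.populations
        )
    if rule == "R-PROJ-ENDPOINTS":
        return any(p.source == EXTERNAL and p.target == EXTERNAL for p in m.projections)
    if rule == "R-PROJ-DENSITY":
        return any(
            p.density is not None and not 0 <= p.density <= 1 for p in m.projections
        )
    if rule == "R-LAYER-NAME":
        return any(l.name not in _ROMAN_VALUES for l in m.layers)
    if rule == "R-LAYER-ORDER":
        return any(
            l.name in _ROMAN_VALUES and l.order_index != _ROMAN_VALUES[l.name]
            for l in m.layers
        )
    if rule == "R-NCR-NOLAYERS":
        ncrs = {r.id for r in m.regions if r.kind == RegionKind.NCR}
        return any(l.area_ref in ncrs for l in m.layers) or any(
            p.layer_ref and p.region_ref in ncrs for p in m.populations
        )
    if rule == "R-UNIT-FOREST":
        counts = {}
        pop_ids = {p.id for p in m.populations}
        for u in m.units:
            for member in u.members:
                if member in pop_ids:
                    counts[member] = counts.get(member, 0) + 1
        return any(c > 1 for c in counts.values())
    if rule == "R-REF-INTEGRITY":
        pop_ids = {p.id for p in m.populations}
        return any(
            end != EXTERNAL and end not in pop_ids
            for p in m.projections for end in (p.source, p.target)
        )
    if rule == "R-NO-COLOR":
        return any(
            "fill_color" in p.extra_attributes for p in m.populations
        )
    if rule == "R-NO-SCALING":
        return any("scale_by" in p.extra_attributes for p in m.projections)
    raise AssertionError(rule)


class TestInjection:
    @pytest.mark.parametrize("rule", sorted(INJECTORS))
    @pytest.mark.parametrize("seed", range(20))
    def test_single_fault_detected_exactly(self, rule, seed):
        """Injecting one violation yields diagnostics for that rule and no
        other, matching an independent naive scan."""
        clean = base_model(seed)
        assert validate_model(clean) == []
        broken = copy.deepcopy(clean)
        INJECTORS[rule](broken)
        assert _oracle(rule, broken), "injector failed to create the fault"
        diags = validate_model(broken)
        assert diags, f"{rule}: fault not detected"
        assert {d.rule_id for d in diags} == {rule}


class TestCleanModels:
    def test_paper_fixtures_validate_clean(self, fixture_model):
        assert validate_model(fixture_model) == []

    def test_empty_model_vacuously_conformant(self):
        assert validate_model(NNSModel()) == []

    def test_zero_errors_implies_strict_construction_succeeds(self):
        """Soundness: a model the validator passes can be rebuilt strictly."""
        m = base_model(5)
        assert not [d for d in validate_model(m) if d.severity == "ERROR"]
        rebuilt = NNSModel(
            populations=m.populations, projections=m.projections, layers=m.layers,
            regions=m.regions, units=m.units, metadata=m.metadata,
        )
        assert rebuilt == m


class TestDiagnostics:
    def test_layer_inside_ncr_is_an_error(self):
        m = base_model(0)
        m.layers.append(Layer("VI", "zz_ncr"))
        diags = validate_model(m)
        assert [d.rule_id for d in diags] == ["R-NCR-NOLAYERS"]
        assert diags[0].severity == "ERROR"
        assert "layer" in diags[0].message

    def test_zero_density_is_a_warning(self):
        m = base_model(1)
        m.projections[0].density = 0.0
        diags = validate_model(m)
        assert [(d.severity, d.rule_id) for d in diags] == [("WARNING", "R-PROJ-DENSITY")]

    def test_stylistic_requests_are_warnings_structural_faults_errors(self):
        m = base_model(2)
        m.populations[0].extra_attributes["fill"] = "#ff0000"
        m.projections[0].target = "ghost"
        diags = validate_model(m)
        assert [d.severity for d in diags] == ["ERROR", "WARNING"]  # sorted severity-first

    def test_report_line_format(self):
        m = base_model(3)
        m.projections[0].target = "ghost"
        report = format_diagnostics(validate_model(m))
        assert report.startswith("ERROR R-REF-INTEGRITY")

    def test_every_diagnostic_cites_a_rulebook_rule(self):
        m = base_model(4)
        for injector in INJECTORS.values():
            injector(m)
        for d in validate_model(m):
            assert d.rule_id in RULE_IDS
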