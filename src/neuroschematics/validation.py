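"""Notation rulebook validation.

Checks an :class:`~neuroschematics.model.NNSModel` against the closed set of
notation rules and returns machine-readable diagnostics.  Validation never
raises: every finding is a :class:`Diagnostic`.  Structural violations are
ERRORs; stylistic requests the notation forbids (color fills,
attribute-proportional glyph scaling) do not corrupt the model and are
WARNINGs, as is a semantically void density of exactly zero.

Rulebook
--------
R-POP-LABEL       population label has >=1 part, uppercase alphanumeric tokens
R-PROJ-ENDPOINTS  one source + one target, never both EXTERNAL
R-PROJ-DENSITY    density within [0, 1]; exactly 0 is a WARNING
R-LAYER-NAME      layer names are roman numerals I..VI, unique per area
R-LAYER-ORDER     layer order index equals its numeral value (highest on top)
R-NCR-NOLAYERS    NCRs must not contain layer boundaries or layered populations
R-UNIT-FOREST     unit membership is a forest; one direct unit per population
R-REF-INTEGRITY   every reference resolves to exactly one element
R-NO-COLOR        no color fills/strokes requested via style attributes
R-NO-SCALING      no attribute-proportional glyph sizes requested
"""

from __future__ import annotations

from dataclasses import dataclass

from neuroschematics.model import (
    EXTERNAL,
    NNSModel,
    RegionKind,
    _TOKEN_RE,
    _ROMAN_VALUES,
)

RULE_IDS = (
    "R-POP-LABEL",
    "R-PROJ-ENDPOINTS",
    "R-PROJ-DENSITY",
    "R-LAYER-NAME",
    "R-LAYER-ORDER",
    "R-NCR-NOLAYERS",
    "R-UNIT-FOREST",
    "R-REF-INTEGRITY",
    "R-NO-COLOR",
    "R-NO-SCALING",
)

#: extra_attributes / metadata keys interpreted as a request for colored
#: rendering — forbidden by the notation ("Colors are not applied").
COLOR_STYLE_KEYS = frozenset(
    {"color", "fill", "fill_color", "stroke_color", "style.color", "style.fill"}
)
#: keys interpreted as a request to scale glyphs by attribute values —
#: forbidden ("no features of graphical elements will be scaled").
SCALING_STYLE_KEYS = frozenset(
    {"scale_by", "size_by", "width_by", "style.scale_by", "style.size_by"}
)


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding, keyed to a notation rule identifier."""

    severity: str  # "ERROR" | "WARNING"
    rule_id: str
    subject: str
    message: str

    def __post_init__(self):
        assert self.rule_id in RULE_IDS, self.rule_id
        assert self.severity in ("ERROR", "WARNING"), self.severity

    def __str__(self) -> str:
        return f"{self.severity} {self.rule_id} {self.subject}: {self.message}"

    def as_dict(self) -> dict:
        return {
            "severity": self.severity,
            "rule_id": self.rule_id,
            "subject": self.subject,
            "message": self.message,
        }


def validate_model(model: NNSModel) -> list[Diagnostic]:
    """Check a model against every rule; return sorted diagnostics.

    An empty list means the model conforms to the whole rulebook.  Order is
    (severity, rule_id, subject) so reports are stable.
    """
    diags: list[Diagnostic] = []
    err = lambda rule, subject, msg: diags.append(Diagnostic("ERROR", rule, subject, msg))
    warn = lambda rule, subject, msg: diags.append(Diagnostic("WARNING", rule, subject, msg))

    pop_ids = [p.id for p in model.populations]
    region_index = {r.id: r for r in model.regions}
    unit_ids = [u.id for u in model.units]
    all_ids = pop_ids + list(region_index) + unit_ids

    # R-REF-INTEGRITY: identifier uniqueness across the document
    seen: set[str] = set()
    for eid in all_ids:
        if eid in seen:
            err("R-REF-INTEGRITY", eid, f"identifier {eid!r} is declared more than once")
        seen.add(eid)
    for pid in pop_ids:
        if pid == EXTERNAL:
            err("R-REF-INTEGRITY", pid, "population id 'EXTERNAL' is a reserved endpoint token")

    pop_set = set(pop_ids)
    unit_set = set(unit_ids)
    layer_index = {(l.area_ref, l.name): l for l in model.layers}

    # populations -------------------------------------------------------
    unit_of_pop: dict[str, list[str]] = {}
    for u in model.units:
        for m in u.members:
            if m in pop_set:
                unit_of_pop.setdefault(m, []).append(u.id)

    for pop in model.populations:
        lab = pop.label
        if not lab.electrophys_class and not lab.morph_class:
            err("R-POP-LABEL", pop.id, "population label has neither class token")
        else:
            for part in (lab.electrophys_class, lab.morph_class):
                if part is not None and not _TOKEN_RE.match(part):
                    err(
                        "R-POP-LABEL",
                        pop.id,
                        f"label token {part!r} is not uppercase alphanumeric",
                    )
        if pop.region_ref is not None and pop.region_ref not in region_index:
            err("R-REF-INTEGRITY", pop.id, f"region_ref {pop.region_ref!r} does not resolve")
        if pop.unit_ref is not None:
            if pop.unit_ref not in unit_set:
                err("R-REF-INTEGRITY", pop.id, f"unit_ref {pop.unit_ref!r} does not resolve")
            elif pop.id not in model.unit(pop.unit_ref).members:
                err(
                    "R-REF-INTEGRITY",
                    pop.id,
                    f"unit {pop.unit_ref!r} does not list population as member",
                )
        if pop.layer_ref is not None:
            region = region_index.get(pop.region_ref) if pop.region_ref else None
            if region is not None and region.kind == RegionKind.NCR:
                err(
                    "R-NCR-NOLAYERS",
                    pop.id,
                    "a population with a layer must live in an area; "
                    "NCRs must not contain layer boundaries",
                )
            elif region is None:
                err(
                    "R-REF-INTEGRITY",
                    pop.id,
                    f"layer_ref {pop.layer_ref!r} set but no area region_ref resolves",
                )
            elif (region.id, pop.layer_ref) not in layer_index:
                err(
                    "R-REF-INTEGRITY",
                    pop.id,
                    f"area {region.id!r} contains no layer {pop.layer_ref!r}",
                )

    # projections -------------------------------------------------------
    for proj in model.projections:
        if proj.source == EXTERNAL and proj.target == EXTERNAL:
            err(
                "R-PROJ-ENDPOINTS",
                proj.id,
                "projections do not branch or join and cannot be external at both ends",
            )
        for end, name in ((proj.source, "source"), (proj.target, "target")):
            if end != EXTERNAL and end not in pop_set:
                err("R-REF-INTEGRITY", proj.id, f"{name} {end!r} does not resolve")
        if proj.density is not None:
            if not (0.0 <= proj.density <= 1.0):
                err(
                    "R-PROJ-DENSITY",
                    proj.id,
                    f"relative connection density {proj.density} outside [0, 1]",
                )
            elif proj.density == 0.0:
                warn(
                    "R-PROJ-DENSITY",
                    proj.id,
                    "connection density of exactly 0 is renderable but semantically void",
                )

    # layers ------------------------------------------------------------
    seen_layers: set[tuple[str, str]] = set()
    for layer in model.layers:
        subject = f"{layer.area_ref}/{layer.name}"
        if layer.name not in _ROMAN_VALUES:
            err(
                "R-LAYER-NAME",
                subject,
                f"layer name {layer.name!r} is not an uppercase roman numeral I..VI",
            )
        else:
            if layer.order_index != _ROMAN_VALUES[layer.name]:
                err(
                    "R-LAYER-ORDER",
                    subject,
                    f"order index {layer.order_index} does not match numeral "
                    f"{layer.name} (highest cortical layer on top)",
                )
        if (layer.area_ref, layer.name) in seen_layers:
            err("R-LAYER-NAME", subject, f"duplicate layer {layer.name!r} in area")
        seen_layers.add((layer.area_ref, layer.name))
        region = region_index.get(layer.area_ref)
        if region is None:
            err("R-REF-INTEGRITY", subject, f"area_ref {layer.area_ref!r} does not resolve")
        elif region.kind == RegionKind.NCR:
            err(
                "R-NCR-NOLAYERS",
                subject,
                f"region {layer.area_ref!r} is an NCR and must not contain layer boundaries",
            )

    # units -------------------------------------------------------------
    for u in model.units:
        for m in u.members:
            if m not in pop_set and m not in unit_set:
                err("R-REF-INTEGRITY", u.id, f"member {m!r} does not resolve")
    for pid, owners in unit_of_pop.items():
        if len(owners) > 1:
            err(
                "R-UNIT-FOREST",
                pid,
                f"population belongs directly to several units: {sorted(owners)}",
            )
    parent_of: dict[str, list[str]] = {}
    for u in model.units:
        for m in u.members:
            if m in unit_set:
                parent_of.setdefault(m, []).append(u.id)
    for uid, parents in parent_of.items():
        if len(parents) > 1:
            err("R-UNIT-FOREST", uid, f"unit has several parent units: {sorted(parents)}")
    # cycle detection over the unit membership graph
    for start in unit_ids:
        node, hops = start, 0
        while node in parent_of and hops <= len(unit_ids):
            node = parent_of[node][0]
            hops += 1
            if node == start:
                err("R-UNIT-FOREST", start, "unit membership contains a cycle")
                break

    # stylistic requests -------------------------------------------------
    def check_style(subject: str, attrs: dict):
        for key in sorted(attrs):
            lk = key.lower()
            if lk in COLOR_STYLE_KEYS:
                warn(
                    "R-NO-COLOR",
                    subject,
                    f"attribute {key!r} requests a color; colors are not applied "
                    "in neural schematics",
                )
            if lk in SCALING_STYLE_KEYS:
                warn(
                    "R-NO-SCALING",
                    subject,
                    f"attribute {key!r} requests attribute-proportional glyph "
                    "scaling, which the notation forbids",
                )

    for pop in model.populations:
        check_style(pop.id, pop.extra_attributes)
    for proj in model.projections:
        check_style(proj.id, proj.extra_attributes)
    check_style("<model>", model.metadata)

    severity_rank = {"ERROR": 0, "WARNING": 1}
    diags.sort(key=lambda d: (severity_rank[d.severity], d.rule_id, d.subject, d.message))
    return diags


def format_diagnostics(diags: list[Diagnostic]) -> str:
    """Line-oriented report: ``severity rule_id subject: message``."""
    return "\n".join(str(d) for d in diags)
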