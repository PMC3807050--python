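"""Core domain model for neural schematics.

A neural schematic describes a large-scale neural network structure (NNS) at
the population/projection level of abstraction: populations of same-class
neurons connected by directed, non-branching projections, optionally annotated
with cortical layers (I–VI), cortical areas, non-cortical regions (NCRs) and
dashed functional units.

Everything below the population level — single neurons, synapse models,
receptor types, plasticity, delays — is deliberately outside the notation.
Such attributes may ride along in ``extra_attributes`` but never influence
geometry or glyph appearance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Optional

#: Sentinel endpoint token for projections entering (inputs) or leaving
#: (outputs) the modeled structure.  Not a population identifier.
EXTERNAL = "EXTERNAL"

_TOKEN_RE = re.compile(r"^[A-Z0-9]+$")

_ROMAN_VALUES = {"I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6}
_ROMAN_BY_VALUE = {v: k for k, v in _ROMAN_VALUES.items()}


class InvalidElementError(ValueError):
    """Raised when a schematic element is constructed in violation of a
    local structural invariant."""


class ModelValidationError(ValueError):
    """Raised when an :class:`NNSModel` fails rule validation at strict
    construction time.  Carries the offending diagnostics."""

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        lines = "; ".join(str(d) for d in self.diagnostics)
        super().__init__(f"model violates notation rules: {lines}")


class ExcitationType(str, Enum):
    """Excitation character shared by every synapse bundled in a projection."""

    EXCITATORY = "excitatory"
    INHIBITORY = "inhibitory"


class RegionKind(str, Enum):
    """Cortical area versus non-cortical region (NCR)."""

    AREA = "area"
    NCR = "ncr"


def roman_to_int(name: str) -> int:
    """Parse an uppercase roman numeral layer name in I..VI."""
    try:
        return _ROMAN_VALUES[name]
    except KeyError:
        raise InvalidElementError(
            f"layer name {name!r} is not an uppercase roman numeral I..VI"
        ) from None


def int_to_roman(value: int) -> str:
    try:
        return _ROMAN_BY_VALUE[value]
    except KeyError:
        raise InvalidElementError(f"no layer numeral for value {value}") from None


@dataclass
class PopulationLabel:
    """Two-part population class label.

    ``electrophys_class`` names the electrophysiological/spiking class (RS,
    FS, POIS, ...) and renders in normal typeset; ``morph_class`` names the
    morphological or other descriptive class (PYR, NPYR, TC, STIM, ...) and
    renders in italics.  At least one part must be present; tokens are
    uppercase alphanumeric without whitespace.
    """

    electrophys_class: Optional[str] = None
    morph_class: Optional[str] = None

    def __post_init__(self):
        if not self.electrophys_class and not self.morph_class:
            raise InvalidElementError("population label needs at least one class token")
        for part in (self.electrophys_class, self.morph_class):
            if part is not None and not _TOKEN_RE.match(part):
                raise InvalidElementError(
                    f"label token {part!r} must be uppercase alphanumeric"
                )

    def text(self) -> str:
        """Plain-text form, e.g. ``RS/PYR``, ``TC``."""
        return "".join(t for t, _ in display_label(self))


def display_label(label: PopulationLabel) -> list[tuple[str, str]]:
    """Resolve a population label into styled spans.

    Returns an ordered list of ``(text, style)`` pairs with style ``"normal"``
    or ``"italic"``.  Both parts present give ``E/M`` with the slash and the
    electrophysiological token in normal typeset and the morphological token
    in italics; a single part is emitted alone in its mandated style.
    """
    e, m = label.electrophys_class, label.morph_class
    if not e and not m:
        raise InvalidElementError("population label needs at least one class token")
    spans: list[tuple[str, str]] = []
    if e:
        spans.append((e, "normal"))
    if e and m:
        spans.append(("/", "normal"))
    if m:
        spans.append((m, "italic"))
    return spans


@dataclass
class Population:
    """A compound of functionally related neurons of one cell class.

    The lowest-level node of the notation, rendered as a solid rectangle.
    ``extra_attributes`` (neuron model parameters, sizes, spatial layout...)
    are carried through serialization but never rendered and never influence
    geometry.
    """

    id: str
    label: PopulationLabel
    layer_ref: Optional[str] = None
    region_ref: Optional[str] = None
    unit_ref: Optional[str] = None
    extra_attributes: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if not self.id:
            raise InvalidElementError("population id must be non-empty")


@dataclass
class Projection:
    """A directed bundle of same-excitation-type synaptic connections.

    One source, one target — projections never branch or join.  ``EXTERNAL``
    as source marks an input to the structure, as target an output; both ends
    external is meaningless and rejected.  ``density`` is the relative
    connection density in [0, 1], the one strength attribute the notation
    renders.
    """

    id: str
    source: str
    target: str
    excitation: ExcitationType
    density: Optional[float] = None
    extra_attributes: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if not self.id:
            raise InvalidElementError("projection id must be non-empty")
        self.excitation = ExcitationType(self.excitation)
        if self.source == EXTERNAL and self.target == EXTERNAL:
            raise InvalidElementError(
                f"projection {self.id}: source and target cannot both be EXTERNAL"
            )
        if self.density is not None and not (0.0 <= self.density <= 1.0):
            raise InvalidElementError(
                f"projection {self.id}: density {self.density} outside [0, 1]"
            )

    @property
    def is_input(self) -> bool:
        return self.source == EXTERNAL

    @property
    def is_output(self) -> bool:
        return self.target == EXTERNAL

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target and self.source != EXTERNAL


@dataclass
class Layer:
    """One cortical lamina of an area, named by an uppercase roman numeral
    I..VI.  ``order_index`` equals the numeral's value; layer I is the
    highest lamina and is drawn on top."""

    name: str
    area_ref: str
    order_index: Optional[int] = None

    def __post_init__(self):
        value = roman_to_int(self.name)
        if self.order_index is None:
            self.order_index = value
        elif self.order_index != value:
            raise InvalidElementError(
                f"layer {self.name}: order_index {self.order_index} != numeral value {value}"
            )

    @property
    def id(self) -> str:
        """Layers are identified by (area, numeral)."""
        return f"{self.area_ref}/{self.name}"


@dataclass
class Region:
    """A cortical area or a non-cortical region (NCR).

    Both render as vertical dotted strips; only areas may be partitioned by
    layer boundaries — an NCR must not contain layers.
    """

    id: str
    kind: RegionKind
    name: str = ""
    display_order: int = 0

    def __post_init__(self):
        if not self.id:
            raise InvalidElementError("region id must be non-empty")
        self.kind = RegionKind(self.kind)


@dataclass
class Unit:
    """A dashed-rectangle functional grouping (column, minicolumn, group...).

    Units may nest sub-units alongside populations; membership must form a
    forest and each population belongs directly to at most one unit.
    """

    id: str
    name: str
    members: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.id:
            raise InvalidElementError("unit id must be non-empty")
        if len(set(self.members)) != len(self.members):
            raise InvalidElementError(f"unit {self.id}: duplicate member references")
        self.members = sorted(self.members)  # membership is a set; keep canonical order


@dataclass
class NNSModel:
    """A complete neural-schematic document.

    Collections are kept sorted by identifier so that equality, serialization
    and layout are order-independent and deterministic.  Construction
    validates against the full notation rulebook unless ``validate=False``
    (used by readers and tests that need to hold a non-conforming model).
    """

    populations: list[Population] = field(default_factory=list)
    projections: list[Projection] = field(default_factory=list)
    layers: list[Layer] = field(default_factory=list)
    regions: list[Region] = field(default_factory=list)
    units: list[Unit] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)
    validate: bool = True

    def __post_init__(self):
        self.populations = sorted(self.populations, key=lambda p: p.id)
        self.projections = sorted(self.projections, key=lambda p: p.id)
        self.layers = sorted(self.layers, key=lambda l: (l.area_ref, l.order_index))
        self.regions = sorted(self.regions, key=lambda r: (r.display_order, r.id))
        self.units = sorted(self.units, key=lambda u: u.id)
        do_validate = self.validate
        self.validate = True  # flag is construction-time only; keep eq stable
        if do_validate:
            from neuroschematics.validation import validate_model

            errors = [d for d in validate_model(self) if d.severity == "ERROR"]
            if errors:
                raise ModelValidationError(errors)

    # -- indexed access -------------------------------------------------

    def population(self, pid: str) -> Population:
        return self._index(self.populations)[pid]

    def region(self, rid: str) -> Region:
        return self._index(self.regions)[rid]

    def unit(self, uid: str) -> Unit:
        return self._index(self.units)[uid]

    @staticmethod
    def _index(elements: Iterable) -> dict:
        return {e.id: e for e in elements}

    def population_ids(self) -> set[str]:
        return {p.id for p in self.populations}

    def layers_of(self, area_id: str) -> list[Layer]:
        return [l for l in self.layers if l.area_ref == area_id]

    def unit_children(self, uid: str) -> list[str]:
        """Member ids of a unit that are themselves units."""
        unit_ids = {u.id for u in self.units}
        return [m for m in self.unit(uid).members if m in unit_ids]

    def is_empty(self) -> bool:
        return not (
            self.populations or self.projections or self.layers or self.regions or self.units
        )


def classify_endpoints(model: NNSModel) -> dict[str, set[str]]:
    """Partition projection ids into ``internal``, ``inputs`` and ``outputs``.

    Inputs are projections with no origin (source ``EXTERNAL``), outputs
    projections with no terminus; everything else is internal.  The three
    sets are disjoint and cover all projections.
    """
    parts: dict[str, set[str]] = {"internal": set(), "inputs": set(), "outputs": set()}
    for proj in model.projections:
        if proj.is_input:
            parts["inputs"].add(proj.id)
        elif proj.is_output:
            parts["outputs"].add(proj.id)
        else:
            parts["internal"].add(proj.id)
    return parts
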