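"""NNSD — the JSON-dialect serialization of a neural schematic model.

Top-level sections: ``format_version``, ``metadata``, ``populations``,
``projections``, ``layers``, ``regions``, ``units``.  External projection
endpoints are serialized as JSON ``null``; densities may be given either as
``density`` (relative, [0,1]) or ``density_percent`` (divided by 100 on
read).  Unknown keys on an element are preserved in its ``attributes`` map
rather than dropped.  Output is deterministic: elements sorted by id, keys
sorted, two-space indent.
"""

from __future__ import annotations

import io as _stdio
import json
from typing import Any, TextIO, Union

from neuroschematics.model import (
    EXTERNAL,
    InvalidElementError,
    Layer,
    ModelValidationError,
    NNSModel,
    Population,
    PopulationLabel,
    Projection,
    Region,
    Unit,
)
from neuroschematics.validation import validate_model

FORMAT_VERSION = "1.0"


class NNSDParseError(ValueError):
    """Malformed NNSD input (syntax or structure)."""


def _as_stream(source: Union[str, TextIO]) -> TextIO:
    if isinstance(source, str):
        return _stdio.StringIO(source)
    return source


def _expect(cond: bool, msg: str):
    if not cond:
        raise NNSDParseError(msg)


def _split_known(entry: dict, known: set[str], what: str) -> dict:
    """Pull unknown keys out of an element record; they are preserved as
    extra attributes instead of being silently discarded."""
    _expect(isinstance(entry, dict), f"{what} entry must be an object")
    extra = dict(entry.get("attributes", {}) or {})
    for key, value in entry.items():
        if key not in known and key != "attributes":
            extra[key] = value
    return extra


def _read_endpoint(value) -> str:
    return EXTERNAL if value is None else str(value)


def read_nnsd(source: Union[str, TextIO]) -> NNSModel:
    """Parse an NNSD document into a validated model.

    Raises :class:`NNSDParseError` on malformed input (with the JSON line/
    column for syntax errors) and :class:`ModelValidationError` naming the
    violated rule when the document parses but breaks the notation rulebook.
    """
    stream = _as_stream(source)
    try:
        doc = json.load(stream)
    except json.JSONDecodeError as exc:
        raise NNSDParseError(
            f"NNSD syntax error at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    _expect(isinstance(doc, dict), "NNSD document must be a JSON object")
    version = doc.get("format_version")
    _expect(isinstance(version, str), "missing or non-string format_version")

    populations = []
    for entry in doc.get("populations", []):
        known = {"id", "label", "layer", "region", "unit"}
        extra = _split_known(entry, known, "population")
        label = entry.get("label", {})
        _expect(isinstance(label, dict), f"population {entry.get('id')}: label must be an object")
        try:
            populations.append(
                Population(
                    id=str(entry["id"]),
                    label=PopulationLabel(
                        electrophys_class=label.get("electrophys"),
                        morph_class=label.get("morph"),
                    ),
                    layer_ref=entry.get("layer"),
                    region_ref=entry.get("region"),
                    unit_ref=entry.get("unit"),
                    extra_attributes=extra,
                )
            )
        except KeyError as exc:
            raise NNSDParseError(f"population entry missing key {exc}") from exc
        except InvalidElementError as exc:
            raise ModelValidationError(
                [_element_diag("R-POP-LABEL", str(entry.get("id", "?")), str(exc))]
            ) from exc

    projections = []
    for entry in doc.get("projections", []):
        known = {"id", "source", "target", "excitation", "density", "density_percent"}
        extra = _split_known(entry, known, "projection")
        density = entry.get("density")
        if density is None and entry.get("density_percent") is not None:
            density = float(entry["density_percent"]) / 100.0
        try:
            projections.append(
                Projection(
                    id=str(entry["id"]),
                    source=_read_endpoint(entry.get("source")),
                    target=_read_endpoint(entry.get("target")),
                    excitation=entry["excitation"],
                    density=density,
                    extra_attributes=extra,
                )
            )
        except KeyError as exc:
            raise NNSDParseError(f"projection entry missing key {exc}") from exc
        except InvalidElementError as exc:
            rule = "R-PROJ-DENSITY" if "density" in str(exc) else "R-PROJ-ENDPOINTS"
            raise ModelValidationError(
                [_element_diag(rule, str(entry.get("id", "?")), str(exc))]
            ) from exc
        except ValueError as exc:
            raise NNSDParseError(f"projection {entry.get('id')}: {exc}") from exc

    layers = []
    for entry in doc.get("layers", []):
        try:
            layers.append(Layer(name=str(entry["name"]), area_ref=str(entry["area"])))
        except KeyError as exc:
            raise NNSDParseError(f"layer entry missing key {exc}") from exc
        except InvalidElementError as exc:
            raise ModelValidationError(
                [_layer_diag(entry, str(exc))]
            ) from exc

    regions = []
    for entry in doc.get("regions", []):
        try:
            regions.append(
                Region(
                    id=str(entry["id"]),
                    kind=entry["kind"],
                    name=str(entry.get("name", "")),
                    display_order=int(entry.get("display_order", 0)),
                )
            )
        except KeyError as exc:
            raise NNSDParseError(f"region entry missing key {exc}") from exc
        except ValueError as exc:
            raise NNSDParseError(f"region {entry.get('id')}: {exc}") from exc

    units = []
    for entry in doc.get("units", []):
        try:
            units.append(
                Unit(
                    id=str(entry["id"]),
                    name=str(entry.get("name", "")),
                    members=[str(m) for m in entry.get("members", [])],
                )
            )
        except KeyError as exc:
            raise NNSDParseError(f"unit entry missing key {exc}") from exc

    return NNSModel(
        populations=populations,
        projections=projections,
        layers=layers,
        regions=regions,
        units=units,
        metadata=dict(doc.get("metadata", {})),
    )


def _element_diag(rule: str, subject: str, msg: str):
    from neuroschematics.validation import Diagnostic

    return Diagnostic("ERROR", rule, subject, msg)


def _layer_diag(entry: dict, msg: str):
    subject = f"{entry.get('area', '?')}/{entry.get('name', '?')}"
    return _element_diag("R-LAYER-NAME", subject, msg)


def _serialize_endpoint(value: str):
    return None if value == EXTERNAL else value


def model_to_document(model: NNSModel) -> dict[str, Any]:
    """Plain-dict form of a model, as written to NNSD files."""
    doc: dict[str, Any] = {"format_version": FORMAT_VERSION}
    if model.metadata:
        doc["metadata"] = model.metadata
    if model.populations:
        doc["populations"] = [
            _drop_empty(
                {
                    "id": p.id,
                    "label": _drop_empty(
                        {
                            "electrophys": p.label.electrophys_class,
                            "morph": p.label.morph_class,
                        }
                    ),
                    "layer": p.layer_ref,
                    "region": p.region_ref,
                    "unit": p.unit_ref,
                    "attributes": p.extra_attributes or None,
                }
            )
            for p in sorted(model.populations, key=lambda p: p.id)
        ]
    if model.projections:
        doc["projections"] = [
            _drop_empty(
                {
                    "id": p.id,
                    "source": _serialize_endpoint(p.source),
                    "target": _serialize_endpoint(p.target),
                    "excitation": p.excitation.value,
                    "density": p.density,
                    "attributes": p.extra_attributes or None,
                },
                keep={"source", "target"},
            )
            for p in sorted(model.projections, key=lambda p: p.id)
        ]
    if model.layers:
        doc["layers"] = [
            {"area": l.area_ref, "name": l.name}
            for l in sorted(model.layers, key=lambda l: (l.area_ref, l.order_index))
        ]
    if model.regions:
        doc["regions"] = [
            {
                "id": r.id,
                "kind": r.kind.value,
                "name": r.name,
                "display_order": r.display_order,
            }
            for r in sorted(model.regions, key=lambda r: (r.display_order, r.id))
        ]
    if model.units:
        doc["units"] = [
            {"id": u.id, "name": u.name, "members": sorted(u.members)}
            for u in sorted(model.units, key=lambda u: u.id)
        ]
    return doc


def _drop_empty(entry: dict, keep: set[str] = frozenset()) -> dict:
    return {k: v for k, v in entry.items() if v is not None or k in keep}


def write_nnsd(model: NNSModel, stream: TextIO | None = None) -> str:
    """Serialize a model to NNSD text (and optionally a stream).

    Refuses to serialize a model with ERROR diagnostics — the diagnostics are
    raised as a :class:`ModelValidationError`.  Output is byte-identical
    across invocations for equal models.
    """
    errors = [d for d in validate_model(model) if d.severity == "ERROR"]
    if errors:
        raise ModelValidationError(errors)
    text = json.dumps(model_to_document(model), indent=2, sort_keys=True) + "\n"
    if stream is not None:
        stream.write(text)
    return text
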