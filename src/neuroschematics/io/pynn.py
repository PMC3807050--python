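"""PyNN-style textual representation of a neural schematic.

The exporter emits a declarative PyNN script: one ``sim.Population`` call per
population and one ``sim.Projection`` per internal projection, with the
excitation type as the receptor target and the connection density as a
fixed-probability connector.  Structural information PyNN has no vocabulary
for — layers, areas, NCRs, units, external inputs/outputs — rides in
``# nns:<kind> <json>`` annotation comments adjacent to the statements, so
the script stays runnable by a PyNN interpreter that knows nothing about
neural schematics.

The importer reads scripts back as *source text* (never executed) restricted
to this declarative subset: imports, ``sim.setup()``/``sim.end()`` calls and
simple assignments of ``sim.Population``/``sim.Projection`` calls with
literal arguments.  Any other construct raises
:class:`UnsupportedConstructError` naming the offending statement.
"""

from __future__ import annotations

import ast
import json
import keyword
import re
from typing import Optional

from neuroschematics.model import (
    EXTERNAL,
    ExcitationType,
    Layer,
    ModelValidationError,
    NNSModel,
    Population,
    PopulationLabel,
    Projection,
    Region,
    Unit,
    classify_endpoints,
)
from neuroschematics.validation import validate_model

_ANNOTATION_RE = re.compile(r"^#\s*nns:([a-z_]+)\s+(.*)$")

_DEFAULT_SIZE = 100


class UnsupportedConstructError(ValueError):
    """A PyNN script statement outside the declarative import subset."""

    def __init__(self, lineno: int, detail: str):
        self.lineno = lineno
        super().__init__(f"unsupported construct at line {lineno}: {detail}")


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _py_identifier(eid: str, taken: set[str]) -> str:
    name = re.sub(r"\W", "_", eid)
    if not name or name[0].isdigit():
        name = "p_" + name
    if keyword.iskeyword(name):
        name += "_"
    base, n = name, 2
    while name in taken:
        name = f"{base}_{n}"
        n += 1
    taken.add(name)
    return name


def _ann(kind: str, payload: dict) -> str:
    return f"# nns:{kind} {json.dumps(payload, sort_keys=True)}"


def export_pynn(model: NNSModel) -> str:
    """Render a validated model as a declarative PyNN script."""
    errors = [d for d in validate_model(model) if d.severity == "ERROR"]
    if errors:
        raise ModelValidationError(errors)

    lines: list[str] = [
        '"""Neural network structure exported from a neural schematic."""',
        "import pyNN.nest as sim",
        "",
        "sim.setup()",
        "",
    ]
    if model.metadata:
        lines.append(_ann("metadata", model.metadata))
        lines.append("")
    for region in model.regions:
        lines.append(
            _ann(
                "region",
                {
                    "id": region.id,
                    "kind": region.kind.value,
                    "name": region.name,
                    "display_order": region.display_order,
                },
            )
        )
    for layer in model.layers:
        lines.append(_ann("layer", {"area": layer.area_ref, "name": layer.name}))
    for unit in model.units:
        lines.append(
            _ann("unit", {"id": unit.id, "name": unit.name, "members": sorted(unit.members)})
        )
    if model.regions or model.layers or model.units:
        lines.append("")

    taken: set[str] = {"sim"}
    varname: dict[str, str] = {}
    for pop in model.populations:
        varname[pop.id] = _py_identifier(pop.id, taken)
    for pop in model.populations:
        payload = {
            "id": pop.id,
            "electrophys": pop.label.electrophys_class,
            "morph": pop.label.morph_class,
            "layer": pop.layer_ref,
            "region": pop.region_ref,
            "unit": pop.unit_ref,
            "attributes": pop.extra_attributes,
        }
        size = pop.extra_attributes.get("size", _DEFAULT_SIZE)
        if not isinstance(size, int):
            size = _DEFAULT_SIZE
        lines.append(_ann("population", payload))
        lines.append(
            f'{varname[pop.id]} = sim.Population({size}, sim.IF_cond_exp(), '
            f'label={pop.label.text()!r})'
        )
        lines.append("")

    parts = classify_endpoints(model)
    proj_vars: set[str] = set(taken)
    for proj in model.projections:
        payload = {"id": proj.id, "attributes": proj.extra_attributes}
        if proj.id in parts["internal"]:
            connector = (
                "sim.AllToAllConnector()"
                if proj.density is None
                else f"sim.FixedProbabilityConnector(p_connect={proj.density!r})"
            )
            lines.append(_ann("projection", payload))
            lines.append(
                f"{_py_identifier(proj.id, proj_vars)} = sim.Projection("
                f"{varname[proj.source]}, {varname[proj.target]}, {connector}, "
                f"receptor_type={proj.excitation.value!r})"
            )
        else:
            kind = "input" if proj.id in parts["inputs"] else "output"
            payload["excitation"] = proj.excitation.value
            payload["density"] = proj.density
            if kind == "input":
                payload["target"] = proj.target
            else:
                payload["source"] = proj.source
            lines.append(_ann(kind, payload))
        lines.append("")

    lines.append("sim.end()")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

def _call_name(call: ast.Call) -> Optional[tuple[str, str]]:
    """Return (object, attribute) for calls like ``sim.Population(...)``."""
    fn = call.func
    if isinstance(fn, ast.Attribute) and isinstance(fn.value, ast.Name):
        return fn.value.id, fn.attr
    return None


def _literal(node: ast.expr, lineno: int):
    try:
        return ast.literal_eval(node)
    except (ValueError, SyntaxError) as exc:
        raise UnsupportedConstructError(lineno, "non-literal argument") from exc


def _parse_label(text: str) -> PopulationLabel:
    # "E/M" splits into the two class tokens; a lone token is taken as the
    # descriptive (morphological/other) class.
    if "/" in text:
        e, m = text.split("/", 1)
        return PopulationLabel(electrophys_class=e or None, morph_class=m or None)
    return PopulationLabel(morph_class=text)


def import_pynn(script: str) -> NNSModel:
    """Reconstruct a model from a declarative PyNN script.

    The script is parsed as source text and never executed.
    """
    try:
        tree = ast.parse(script)
    except SyntaxError as exc:
        raise UnsupportedConstructError(exc.lineno or 0, f"syntax error: {exc.msg}") from exc

    # annotations, keyed by line number
    annotations: list[tuple[int, str, dict]] = []
    for lineno, raw in enumerate(script.splitlines(), start=1):
        m = _ANNOTATION_RE.match(raw.strip())
        if m:
            try:
                payload = json.loads(m.group(2))
            except json.JSONDecodeError as exc:
                raise UnsupportedConstructError(
                    lineno, f"malformed nns annotation: {exc.msg}"
                ) from exc
            annotations.append((lineno, m.group(1), payload))

    metadata: dict = {}
    regions: list[Region] = []
    layers: list[Layer] = []
    units: list[Unit] = []
    populations: list[Population] = []
    projections: list[Projection] = []
    element_ann: dict[int, tuple[str, dict]] = {}

    for lineno, kind, payload in annotations:
        if kind == "metadata":
            metadata.update(payload)
        elif kind == "region":
            regions.append(
                Region(
                    id=payload["id"],
                    kind=payload["kind"],
                    name=payload.get("name", ""),
                    display_order=int(payload.get("display_order", 0)),
                )
            )
        elif kind == "layer":
            layers.append(Layer(name=payload["name"], area_ref=payload["area"]))
        elif kind == "unit":
            units.append(
                Unit(
                    id=payload["id"],
                    name=payload.get("name", ""),
                    members=list(payload.get("members", [])),
                )
            )
        elif kind in ("input", "output"):
            projections.append(
                Projection(
                    id=payload["id"],
                    source=EXTERNAL if kind == "input" else payload["source"],
                    target=payload["target"] if kind == "input" else EXTERNAL,
                    excitation=ExcitationType(payload["excitation"]),
                    density=payload.get("density"),
                    extra_attributes=dict(payload.get("attributes", {})),
                )
            )
        elif kind in ("population", "projection"):
            element_ann[lineno] = (kind, payload)
        else:
            raise UnsupportedConstructError(lineno, f"unknown annotation kind {kind!r}")

    def annotation_for(stmt_lineno: int, want: str) -> Optional[dict]:
        best = None
        for lineno, (kind, payload) in element_ann.items():
            if kind == want and lineno < stmt_lineno and (best is None or lineno > best[0]):
                best = (lineno, payload)
        if best is not None:
            del element_ann[best[0]]
            return best[1]
        return None

    pop_by_var: dict[str, str] = {}

    for stmt in tree.body:
        if isinstance(stmt, (ast.Import, ast.ImportFrom)):
            continue
        if isinstance(stmt, ast.Expr) and isinstance(stmt.value, ast.Constant) and isinstance(
            stmt.value.value, str
        ):
            continue  # module docstring
        if isinstance(stmt, ast.Expr) and isinstance(stmt.value, ast.Call):
            named = _call_name(stmt.value)
            if named and named[1] in ("setup", "end"):
                continue
            raise UnsupportedConstructError(stmt.lineno, "only sim.setup()/sim.end() calls")
        if not isinstance(stmt, ast.Assign):
            raise UnsupportedConstructError(
                stmt.lineno, f"statement type {type(stmt).__name__} outside declarative subset"
            )
        if len(stmt.targets) != 1 or not isinstance(stmt.targets[0], ast.Name):
            raise UnsupportedConstructError(stmt.lineno, "assignment must bind a single name")
        if not isinstance(stmt.value, ast.Call):
            raise UnsupportedConstructError(stmt.lineno, "assignment value must be a call")
        named = _call_name(stmt.value)
        if named is None:
            raise UnsupportedConstructError(stmt.lineno, "call must be of the form sim.<X>(...)")
        target_var = stmt.targets[0].id
        _, attr = named

        if attr == "Population":
            ann = annotation_for(stmt.lineno, "population") or {}
            size = _literal(stmt.value.args[0], stmt.lineno) if stmt.value.args else _DEFAULT_SIZE
            label_kw = next((k for k in stmt.value.keywords if k.arg == "label"), None)
            if ann:
                label = PopulationLabel(
                    electrophys_class=ann.get("electrophys"),
                    morph_class=ann.get("morph"),
                )
                attrs = dict(ann.get("attributes", {}))
                pid = ann["id"]
            else:
                if label_kw is None:
                    raise UnsupportedConstructError(stmt.lineno, "population needs a label")
                label = _parse_label(_literal(label_kw.value, stmt.lineno))
                attrs = {"size": size}
                pid = target_var
            populations.append(
                Population(
                    id=pid,
                    label=label,
                    layer_ref=ann.get("layer"),
                    region_ref=ann.get("region"),
                    unit_ref=ann.get("unit"),
                    extra_attributes=attrs,
                )
            )
            pop_by_var[target_var] = pid
        elif attr == "Projection":
            ann = annotation_for(stmt.lineno, "projection") or {}
            if len(stmt.value.args) < 3:
                raise UnsupportedConstructError(
                    stmt.lineno, "projection needs (pre, post, connector)"
                )
            pre, post, connector = stmt.value.args[:3]
            if not (isinstance(pre, ast.Name) and isinstance(post, ast.Name)):
                raise UnsupportedConstructError(
                    stmt.lineno, "projection endpoints must be population names"
                )
            try:
                source = pop_by_var[pre.id]
                target = pop_by_var[post.id]
            except KeyError as exc:
                raise UnsupportedConstructError(
                    stmt.lineno, f"unknown population variable {exc}"
                ) from exc
            density = None
            if isinstance(connector, ast.Call):
                cname = _call_name(connector)
                if cname and cname[1] == "FixedProbabilityConnector":
                    for kw in connector.keywords:
                        if kw.arg == "p_connect":
                            density = float(_literal(kw.value, stmt.lineno))
                elif cname and cname[1] == "AllToAllConnector":
                    density = None
                else:
                    raise UnsupportedConstructError(
                        stmt.lineno, f"unsupported connector {ast.dump(connector.func)}"
                    )
            receptor = next(
                (k for k in stmt.value.keywords if k.arg == "receptor_type"), None
            )
            excitation = (
                ExcitationType(_literal(receptor.value, stmt.lineno))
                if receptor is not None
                else ExcitationType.EXCITATORY
            )
            projections.append(
                Projection(
                    id=ann.get("id", target_var),
                    source=source,
                    target=target,
                    excitation=excitation,
                    density=density,
                    extra_attributes=dict(ann.get("attributes", {})),
                )
            )
        else:
            raise UnsupportedConstructError(
                stmt.lineno, f"call sim.{attr}(...) outside declarative subset"
            )

    return NNSModel(
        populations=populations,
        projections=projections,
        layers=layers,
        regions=regions,
        units=units,
        metadata=metadata,
    )
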