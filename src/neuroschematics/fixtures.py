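"""Built-in example schematics and a seeded random-model generator.

The fixed fixtures reproduce classic population-level circuit drawings
redrawn in the neural-schematic grammar: a single population with its four
canonical projections, a thalamocortical loop, a synfire chain with
feed-forward inhibition, and a hypercolumn of an attractor-memory cortical
model.  The random generator produces structurally valid models with
controlled element counts for property testing.
"""

from __future__ import annotations

import random
from enum import Enum

from neuroschematics.model import (
    EXTERNAL,
    ExcitationType,
    Layer,
    NNSModel,
    Population,
    PopulationLabel,
    Projection,
    Region,
    RegionKind,
    Unit,
    int_to_roman,
)

EXC = ExcitationType.EXCITATORY
INH = ExcitationType.INHIBITORY


class FixtureId(str, Enum):
    """Closed enumeration of the built-in example schematics."""

    FIG7_POPULATIONS = "FIG7_POPULATIONS"
    FIG8_PROJECTIONS = "FIG8_PROJECTIONS"
    FIG10_THALAMOCORTICAL = "FIG10_THALAMOCORTICAL"
    FIG11_SYNFIRE_FFI = "FIG11_SYNFIRE_FFI"
    FIG12_HYPERCOLUMN = "FIG12_HYPERCOLUMN"


class GeneratorError(ValueError):
    """Infeasible random-model parameter combination."""


def build_fixture(fid: FixtureId | str) -> NNSModel:
    """Materialize one of the built-in example schematics.

    Every fixture validates clean against the full rulebook.
    """
    fid = FixtureId(fid)
    return _BUILDERS[fid]()


def _fig7() -> NNSModel:
    """Three label-style examples: a POIS stimulus population (spiking-
    behavior class only), an RS/PYR cortical population, and a UNI motor
    population (morphological class only)."""
    return NNSModel(
        populations=[
            Population("pois", PopulationLabel(electrophys_class="POIS")),
            Population("pyr", PopulationLabel("RS", "PYR")),
            Population("uni", PopulationLabel(morph_class="UNI")),
        ],
        metadata={"title": "Population symbol examples"},
    )


def _fig8() -> NNSModel:
    """One RS/PYR population with its four canonical projections: an
    excitatory input (density 0.5), an inhibitory input (0.1), an excitatory
    self-projection (0.2) and an additional output (0.2)."""
    return NNSModel(
        populations=[Population("pyr", PopulationLabel("RS", "PYR"))],
        projections=[
            Projection("in_exc", EXTERNAL, "pyr", EXC, density=0.5),
            Projection("in_inh", EXTERNAL, "pyr", INH, density=0.1),
            Projection("self_exc", "pyr", "pyr", EXC, density=0.2),
            Projection("out", "pyr", EXTERNAL, EXC, density=0.2),
        ],
        metadata={"title": "Projection symbol examples"},
    )


def _fig10() -> NNSModel:
    """Thalamocortical loop: a thalamus NCR housing TC (thalamocortical
    relay) and RE (reticular) populations, and cortical Area 5 whose layer
    VI houses RS/PYR and FS/NPYR populations.

    The projection topology follows the population-level prose of the
    source circuit (thalamocortical and corticothalamic excitation,
    reticular inhibition with a reticular self-projection, local cortical
    recurrence and inhibition).  Connection densities are not carried: the
    original prints them at figure resolution only, so they are left absent
    here.  The two stimulus afferents (synthetic placement: one onto TC,
    one onto the cortical pyramidal population) stand for the stimulus
    projections added in the redrawn schematic.
    """
    thal, a5 = "thalamus", "area5"
    return NNSModel(
        regions=[
            Region(thal, RegionKind.NCR, "Thalamus", display_order=0),
            Region(a5, RegionKind.AREA, "Area 5", display_order=1),
        ],
        layers=[Layer("VI", a5)],
        populations=[
            Population("tc", PopulationLabel(morph_class="TC"), region_ref=thal),
            Population("re", PopulationLabel(morph_class="RE"), region_ref=thal),
            Population("pyr", PopulationLabel("RS", "PYR"), layer_ref="VI", region_ref=a5),
            Population("npyr", PopulationLabel("FS", "NPYR"), layer_ref="VI", region_ref=a5),
        ],
        projections=[
            Projection("tc_pyr", "tc", "pyr", EXC),
            Projection("tc_npyr", "tc", "npyr", EXC),
            Projection("tc_re", "tc", "re", EXC),
            Projection("pyr_tc", "pyr", "tc", EXC),
            Projection("pyr_re", "pyr", "re", EXC),
            Projection("pyr_npyr", "pyr", "npyr", EXC),
            Projection("pyr_pyr", "pyr", "pyr", EXC),
            Projection("npyr_pyr", "npyr", "pyr", INH),
            Projection("re_tc", "re", "tc", INH),
            Projection("re_re", "re", "re", INH),
            Projection("stim_tc", EXTERNAL, "tc", EXC),
            Projection("stim_pyr", EXTERNAL, "pyr", EXC),
        ],
        metadata={"title": "Thalamocortical regions"},
    )


def _fig11() -> NNSModel:
    """Synfire chain with feed-forward inhibition, drawn with three logical
    group units.  Each group holds an RS/PYR population and an FS/NPYR
    population; the FS population inhibits its group's RS population, each
    RS population excites the next group's RS and FS populations, and a
    stimulus population drives the first group.  Densities are deferred to
    the source model's reference and therefore absent."""
    populations = [Population("stim", PopulationLabel(morph_class="STIM"))]
    projections = []
    units = []
    for i in (1, 2, 3):
        rs, fs = f"rs{i}", f"fs{i}"
        gid = f"group{i}"
        populations += [
            Population(rs, PopulationLabel("RS", "PYR"), unit_ref=gid),
            Population(fs, PopulationLabel("FS", "NPYR"), unit_ref=gid),
        ]
        units.append(Unit(gid, name="group", members=[rs, fs]))
        projections.append(Projection(f"ffi{i}", fs, rs, INH))
        if i < 3:
            projections.append(Projection(f"ff_rs{i}", rs, f"rs{i + 1}", EXC))
            projections.append(Projection(f"ff_fs{i}", rs, f"fs{i + 1}", EXC))
    projections += [
        Projection("stim_rs1", "stim", "rs1", EXC),
        Projection("stim_fs1", "stim", "fs1", EXC),
        Projection("drive", EXTERNAL, "stim", EXC),
    ]
    return NNSModel(
        populations=populations,
        projections=projections,
        units=units,
        metadata={"title": "Synfire chain with feed-forward inhibition"},
    )


def _fig12() -> NNSModel:
    """One hypercolumn of an attractor-memory model of neocortical layers
    II/III.  Two minicolumn units (each an RS/NPYR double-bouquet population
    in layer II and an RS/PYR pyramidal population in layer III) are housed
    together with an FS/NPYR basket population in a hypercolumn unit; a STIM
    population abstracts the layer IV input and sits outside the
    hypercolumn (the source leaves its placement unstated).

    The source drawing shows layer information only, so the single
    enclosing area is anonymous (empty name) and region delimiters are
    suppressed at render time.  Wiring is synthesized from the model
    prose: local pyramidal recurrence, pyramidal drive onto the basket
    population, basket lateral inhibition onto every minicolumn, and
    cross-minicolumn pyramidal-to-double-bouquet excitation with local
    double-bouquet inhibition.
    """
    cortex = "cortex"
    hyper = "hypercolumn"
    populations = [Population("stim", PopulationLabel(morph_class="STIM"), region_ref=cortex)]
    projections = [Projection("drive", EXTERNAL, "stim", EXC)]
    units = []
    minis = ("m1", "m2")
    for mid in minis:
        rsnp, pyr = f"{mid}_rsnp", f"{mid}_pyr"
        populations += [
            Population(rsnp, PopulationLabel("RS", "NPYR"), layer_ref="II",
                       region_ref=cortex, unit_ref=mid),
            Population(pyr, PopulationLabel("RS", "PYR"), layer_ref="III",
                       region_ref=cortex, unit_ref=mid),
        ]
        units.append(Unit(mid, name="Minicolumn", members=[rsnp, pyr]))
        projections += [
            Projection(f"{mid}_recur", pyr, pyr, EXC),
            Projection(f"{mid}_pyr_basket", pyr, "basket", EXC),
            Projection(f"basket_{mid}", "basket", pyr, INH),
            Projection(f"{mid}_rsnp_pyr", rsnp, pyr, INH),
            Projection(f"stim_{mid}", "stim", pyr, EXC),
        ]
    projections += [
        Projection("m1_pyr_m2_rsnp", "m1_pyr", "m2_rsnp", EXC),
        Projection("m2_pyr_m1_rsnp", "m2_pyr", "m1_rsnp", EXC),
    ]
    populations.append(
        Population("basket", PopulationLabel("FS", "NPYR"), layer_ref="III",
                   region_ref=cortex, unit_ref=hyper)
    )
    units.append(Unit(hyper, name="Hypercolumn", members=["m1", "m2", "basket"]))
    return NNSModel(
        populations=populations,
        projections=projections,
        layers=[Layer("II", cortex), Layer("III", cortex)],
        regions=[Region(cortex, RegionKind.AREA, name="", display_order=0)],
        units=units,
        metadata={"title": "Associative memory hypercolumn"},
    )


_BUILDERS = {
    FixtureId.FIG7_POPULATIONS: _fig7,
    FixtureId.FIG8_PROJECTIONS: _fig8,
    FixtureId.FIG10_THALAMOCORTICAL: _fig10,
    FixtureId.FIG11_SYNFIRE_FFI: _fig11,
    FixtureId.FIG12_HYPERCOLUMN: _fig12,
}

_ELECTRO_POOL = ("RS", "FS", "IB", "CH", "LTS", "POIS")
_MORPH_POOL = ("PYR", "NPYR", "TC", "RE", "STIM", "UNI", "SS")


def random_model(
    seed: int,
    n_pop: int = 10,
    n_proj: int = 20,
    n_layers: int = 0,
    n_regions: int = 0,
    n_units: int = 0,
    p_inhibitory: float = 0.3,
    p_external: float = 0.1,
) -> NNSModel:
    """Generate a reproducible, rule-conforming random model.

    Element counts are exact; densities are sampled uniformly on (0, 1];
    layer/region/unit assignments are drawn uniformly among valid choices
    only.  Raises :class:`GeneratorError` on infeasible combinations
    (layers without an area, units without populations to anchor them,
    projections without populations).
    """
    if min(n_pop, n_proj, n_layers, n_regions, n_units) < 0:
        raise GeneratorError("element counts must be non-negative")
    if not (0 <= p_inhibitory <= 1 and 0 <= p_external <= 1):
        raise GeneratorError("probabilities must lie in [0, 1]")
    if n_layers > 0 and n_regions == 0:
        raise GeneratorError("layers require at least one area region")
    if n_proj > 0 and n_pop == 0:
        raise GeneratorError("projections require populations")
    if n_units > 0 and n_pop < n_units:
        raise GeneratorError("each unit needs at least one member population")

    rng = random.Random(seed)

    regions: list[Region] = []
    areas: list[str] = []
    for i in range(n_regions):
        # guarantee enough areas for the requested layers (max 6 per area)
        need_area = n_layers > 0 and (
            len(areas) * 6 < n_layers and (n_regions - i) * 6 >= n_layers - len(areas) * 6
        )
        kind = RegionKind.AREA if need_area or rng.random() < 0.6 else RegionKind.NCR
        rid = f"r{i}"
        regions.append(Region(rid, kind, name=f"Region {i}", display_order=i))
        if kind == RegionKind.AREA:
            areas.append(rid)
    if n_layers > len(areas) * 6:
        raise GeneratorError("more layers requested than areas can hold (six each)")

    layers: list[Layer] = []
    per_area: dict[str, int] = {a: 0 for a in areas}
    for _ in range(n_layers):
        open_areas = [a for a in areas if per_area[a] < 6]
        area = rng.choice(open_areas)
        per_area[area] += 1
        layers.append(Layer(int_to_roman(per_area[area]), area))

    populations: list[Population] = []
    for i in range(n_pop):
        style = rng.randrange(3)
        label = PopulationLabel(
            electrophys_class=rng.choice(_ELECTRO_POOL) if style != 1 else None,
            morph_class=rng.choice(_MORPH_POOL) if style != 0 else None,
        )
        region_ref = rng.choice([None] + [r.id for r in regions]) if regions else None
        layer_ref = None
        if region_ref in per_area and per_area[region_ref] > 0 and rng.random() < 0.7:
            layer_ref = int_to_roman(rng.randrange(per_area[region_ref]) + 1)
        populations.append(
            Population(f"p{i}", label, layer_ref=layer_ref, region_ref=region_ref)
        )

    units: list[Unit] = []
    if n_units:
        # spread populations over units; every unit gets at least one member,
        # each population joins at most one unit directly
        members: dict[str, list[str]] = {f"u{i}": [] for i in range(n_units)}
        pool = [p.id for p in populations]
        rng.shuffle(pool)
        for i, uid in enumerate(members):
            members[uid].append(pool[i])
        for pid in pool[n_units:]:
            if rng.random() < 0.5:
                members[rng.choice(sorted(members))].append(pid)
        # occasional nesting, always acyclic: a unit may join a lower-index unit
        parents: dict[str, str] = {}
        for i in range(1, n_units):
            if rng.random() < 0.3:
                parent = f"u{rng.randrange(i)}"
                parents[f"u{i}"] = parent
                members[parent].append(f"u{i}")
        pop_owner = {m: uid for uid, ms in members.items() for m in ms}
        for p in populations:
            p.unit_ref = pop_owner.get(p.id)
        units = [Unit(uid, name=f"unit {uid[1:]}", members=sorted(ms))
                 for uid, ms in members.items()]

    projections: list[Projection] = []
    pop_ids = [p.id for p in populations]
    for i in range(n_proj):
        excitation = INH if rng.random() < p_inhibitory else EXC
        density = rng.uniform(0.0, 1.0)
        density = density if density > 0 else 1.0  # uniform on (0, 1]
        if rng.random() < p_external:
            if rng.random() < 0.5:
                source, target = EXTERNAL, rng.choice(pop_ids)
            else:
                source, target = rng.choice(pop_ids), EXTERNAL
        else:
            source, target = rng.choice(pop_ids), rng.choice(pop_ids)
        projections.append(Projection(f"j{i}", source, target, excitation, density=density))

    return NNSModel(
        populations=populations,
        projections=projections,
        layers=layers,
        regions=regions,
        units=units,
        metadata={"seed": seed},
    )
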