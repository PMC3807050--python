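# Methods

## The notation and its data model

A neural network structure (NNS) is modeled at the population/projection
level: a **population** is a compound of functionally related neurons of one
morphological/electrophysiological class; a **projection** is a directed
bundle of synaptic connections between two populations in which every
synapse shares one excitation type (excitatory or inhibitory). Projections
have exactly one source and one target — they never branch or join. A
projection whose source is the reserved `EXTERNAL` token is an input to the
structure; one whose target is `EXTERNAL` is an output; both ends external
is rejected. Self-projections are ordinary.

Spatial annotation is optional and three-fold: cortical **layers** I–VI
(order fixed by the numeral, lamina I highest), **areas** (functional
cortical partitions that may contain layers) and **NCRs** (non-cortical
regions, drawn like areas but barred from containing layer boundaries), and
**units** (functional groupings that may nest sub-units alongside
populations; membership must form a forest, and a population belongs to at
most one unit directly — the notation leaves overlapping membership
unspecified, and we forbid it as the conservative reading).

Everything below this abstraction level — neuron models, receptor types,
synaptic weights, delays, plasticity — is carried opaquely in
`extra_attributes` and never rendered, and never influences geometry. The
single rendered strength attribute is the relative connection density in
[0, 1]; percentage inputs are accepted in the file format (`density_percent`)
and divided by 100 on read.

## The rulebook

Validation is total (never raises; every finding is a diagnostic) and the
rule set is closed: `R-POP-LABEL`, `R-PROJ-ENDPOINTS`, `R-PROJ-DENSITY`,
`R-LAYER-NAME`, `R-LAYER-ORDER`, `R-NCR-NOLAYERS`, `R-UNIT-FOREST`,
`R-REF-INTEGRITY`, `R-NO-COLOR`, `R-NO-SCALING`. Structural violations are
ERRORs; stylistic requests the grammar forbids (color fills,
attribute-proportional glyph scaling, recognized through a fixed set of
attribute keys such as `fill_color` and `scale_by`) are WARNINGs because
they do not corrupt the model, as is a density of exactly 0 (renderable but
semantically void — the notation is silent, so we flag rather than reject).
Diagnostics sort by (severity, rule, subject) for stable reports. Strict
model construction re-runs the validator and raises on any ERROR, so a
model object in normal flow is conformant by construction.

## Layout algorithm

The notation constrains topology, not metrics (shapes are explicitly of
arbitrary size), so the layout engine is free in its placement strategy and
must only honor the conventions. It is a pure function of (model, config);
there is no randomness anywhere.

1. **Grid scaffold.** Columns: one vertical strip per region in display
   order, plus a trailing strip for region-less populations. Rows: one
   horizontal band per distinct layer numeral in use, sorted ascending
   (lamina I on top), plus a trailing band for layer-less populations.
   Every population hashes to one (band, strip) cell.
2. **Within-cell order.** Populations are grouped by their unit-membership
   chain first — with populations that sit directly in a parent unit
   ordered after their sibling sub-units, so dashed boxes stay contiguous
   and never swallow non-members — then by longest-path rank over the
   cell-internal projection graph (cycles are condensed first), ties broken
   by identifier. Rank ordering makes in-cell flow run left-to-right,
   matching the left-in/right-out convention.
3. **Metrics.** Box width grows with the label length via a character-count
   heuristic (no font metrics, hence no font files at render time); heights
   are uniform. Extra clearance (two unit margins) is inserted where the
   unit chain changes between horizontal neighbours. Band height and strip
   widths derive from content, so the configuration cannot become
   infeasible by crowding; config validation instead rejects non-positive
   lengths and a `loop_margin` that would not fit inside `band_gap`.
4. **Routing.** Orthogonal polylines. Attachment points spread along the
   mandated edge (incoming left, outgoing right), ordered by projection id.
   Forward routes drop onto a vertical track in the channel left of the
   target; backward routes detour below both boxes; self-loops leave the
   right edge, cross over the top of the box at `loop_margin`, and re-enter
   the left edge. Tracks are allocated greedily in projection-id order —
   determinism and testability are preferred over crossing minimization,
   which is out of scope. Inputs start at the canvas's left margin;
   outputs run to its right margin.
5. **Units.** A unit box is the bounding rectangle of its member boxes
   (children computed first) expanded by `unit_margin`, which guarantees
   the nesting margin by construction. Non-nested unit boxes may overlap
   only when memberships genuinely interleave across cells; that case is
   reported as a layout warning, not an error.
6. **Degenerate inputs.** The empty model yields a zero-extent canvas. A
   unit with no placeable members receives a small dashed box below the
   content and a warning.

Default metrics (abstract units, rendered 1:1 as SVG user units): minimum
box 64×32, band gap 22, column gap 48, channel spacing 8, unit margin 10,
loop margin 12, font size 12. They were chosen once for legibility at
print scale and are overridable via `LayoutConfig` or the CLI config file.

## Rendering

SVG 1.1 via the stdlib XML tree; output is byte-deterministic (stable
element order, fixed two-decimal coordinate rounding). One stroke width for
every element class; strokes black, fills none; no arrowhead markers exist
in the document. Dash patterns appear on exactly three element families:
dotted for layer lines and region delimiters, dashed for unit rectangles.
The inhibitory terminator is an unfilled circle tangent to the target's
left edge; the grammar fixes it as *empty* but not its size, so the radius
defaults to three stroke widths. Density labels sit above the midpoint of
the path's middle segment — the grammar does not say where the label goes
relative to crossings, so this is a package convention. A model whose only
region is a single anonymous area (used for layer-only schematics, e.g.
the hypercolumn example) suppresses region delimiters and labels.

## Textual representations

**NNSD** is this package's JSON dialect (see `docs/nnsd-format.md`):
elements sorted by id, keys sorted, external endpoints as `null`, unknown
element keys preserved in `attributes` rather than dropped. `read ∘ write`
is the identity on valid models and writing is byte-deterministic; an
invalid model is refused with its diagnostics.

**PyNN** serves as the interchange script form: one `sim.Population` per
population, one `sim.Projection` per internal projection (excitation type
as `receptor_type`, density as a `FixedProbabilityConnector` probability;
absent density maps to `AllToAllConnector`). PyNN has no vocabulary for
layers, areas, NCRs, units, or external endpoints, so that structure rides
in `# nns:<kind> {json}` comment annotations adjacent to the statements —
the script stays runnable by a PyNN-aware interpreter that ignores
comments. The importer parses scripts as *source text* (never executes
them) and accepts only the declarative subset the exporter emits: imports,
`sim.setup()`/`sim.end()`, and single-name assignments of
`sim.Population`/`sim.Projection` calls with literal arguments. Anything
else raises an unsupported-construct error naming the statement.
`import ∘ export` is the identity on this subset. Population sizes are
taken from the `size` extra attribute (default 100); a hand-written
script's lone label token is read as the descriptive (italic) class, since
a bare PyNN label cannot distinguish the two classes.

## Built-in examples and the random generator

Five fixture schematics exercise every symbol of the grammar: the
population label examples (POIS, RS/*PYR*, *UNI*); the four-projection
single-population example with densities 0.5/0.1/0.2/0.2; a
thalamocortical circuit (thalamus NCR with *TC* and *RE*, cortical area 5
layer VI with RS/*PYR* and FS/*NPYR*, reticular and cortical inhibition,
stimulus inputs); a three-group synfire chain with feed-forward inhibition;
and an attractor-memory hypercolumn (two minicolumn units plus a basket
population nested in a hypercolumn unit, layers II/III, STIM drive).
Where the source circuits print densities only at unreadable figure
resolution, the fixtures leave them absent rather than inventing numbers;
synthesized details (stimulus attachment points in the thalamocortical
fixture, the exact cross-minicolumn wiring, STIM placed outside the
hypercolumn) are noted in the fixture docstrings.

`random_model(seed, ...)` generates rule-conforming models with exact
element counts for property testing: labels drawn from class-token pools,
layer/region/unit assignments uniform among valid choices only (layers
only in areas, at most six per area, every unit non-empty, one direct unit
per population, acyclic nesting), densities uniform on (0, 1], inhibitory
and external probabilities as given. Infeasible parameter combinations
raise a generator error. It emulates structural variety, not biological
statistics — passing property suites demonstrates geometric and
serialization correctness on arbitrary valid structures, not that real
cortical models look like these.

## Known limitations

* Crossing minimization is not attempted; dense recurrent models route
  correctly but not beautifully.
* Projections between layered sub-bands of two different areas are routed
  by the same channel scheme but have no reference drawing to compare
  against.
* Collapsible hierarchical units and 3-D spatial extensions are outside
  the notation's current scope.
* Text extents use a character-count heuristic; extreme font substitutions
  may overflow a box slightly without affecting geometry checks.
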