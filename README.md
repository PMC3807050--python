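# neuroschematics

Schematic diagrams for large-scale neural network structures (NNSs), built
the way electrical engineers draw circuits: a small, fixed visual grammar
instead of ad-hoc box-and-arrow figures.

Computational neuroscience communicates population-level network models —
populations of same-class neurons wired by directed projection bundles —
through figures whose styles conflict from paper to paper: arrows mean
excitation in one figure and inhibition in the next, color codings collide,
node shapes are scaled by arbitrary attributes. This package implements a
*neural schematic* notation with a single deterministic rendering so that a
model drawn twice looks the same twice:

* **populations** — solid unfilled rectangles labeled `E/M`, where `E` is
  the electrophysiological/spiking class (RS, FS, POIS, ...) in normal
  typeset and `M` the morphological or other descriptive class (*PYR*,
  *NPYR*, *TC*, ...) in italics;
* **projections** — solid polylines that *leave a population on its right
  edge and enter on the left edge*; this convention replaces arrowheads
  entirely. An empty circle at the terminus marks an inhibitory projection;
  the optional label is the relative connection density in [0, 1], the one
  strength attribute the notation renders. Projections never branch or
  join; a projection without an origin is an input to the structure,
  without a terminus an output;
* **layers** — cortical laminae I–VI as dotted horizontal bands, highest
  lamina on top, named in roman numerals at the right edge;
* **areas and NCRs** — vertical dotted strips with monospace names; a
  non-cortical region (NCR) is drawn like an area but may never contain
  layer boundaries;
* **units** — dashed rectangles grouping populations functionally
  (columns, minicolumns, synfire groups), nestable alongside populations.

No colors, no glyph sizes proportional to attribute values, one stroke
width for everything.

The package provides the validated data model, a JSON textual format
(**NNSD**), a rulebook validator with machine-readable diagnostics, a
deterministic orthogonal layout engine, an SVG 1.1 renderer, interchange
with declarative **PyNN** scripts, built-in example schematics, and a CLI.

## Worked example

Build the single-population projection example (one RS/*PYR* population
with an excitatory input of density 0.5, an inhibitory input of 0.1, an
excitatory self-projection of 0.2 and an output of 0.2), classify its
projections and render it:

```python
import neuroschematics as ns

model = ns.build_fixture("FIG8_PROJECTIONS")

parts = ns.classify_endpoints(model)
print({k: sorted(v) for k, v in parts.items()})
# {'internal': ['self_exc'], 'inputs': ['in_exc', 'in_inh'], 'outputs': ['out']}

print(ns.display_label(model.populations[0].label))
# [('RS', 'normal'), ('/', 'normal'), ('PYR', 'italic')]

layout = ns.compute_layout(model)
svg = ns.render_svg(layout, model)
print(svg.count("<circle"), svg.count("<polyline"))
# 1 4
```

The two `inputs` are the origin-free projections, `out` is the
terminus-free one, and the self-projection is the only internal edge. The
rendered document contains four projection polylines and exactly one empty
terminator circle — the inhibitory input.

The same model on the command line:

```sh
neuroschematics demo FIG8_PROJECTIONS -o out/
neuroschematics validate out/fig8_projections.nnsd.json   # exit 0, silent
neuroschematics render out/fig8_projections.nnsd.json -o fig8.svg
neuroschematics convert out/fig8_projections.nnsd.json --to pynn -o fig8.py
```

`validate` exits 1 when the rulebook is violated and prints diagnostics
such as `ERROR R-NCR-NOLAYERS thalamus/VI: ...` to stderr; `convert` maps
between NNSD and the PyNN representation losslessly in both directions.

Ready-made NNSD documents for all five built-in schematics live under
`examples/`; regenerate their SVGs with `neuroschematics render`.

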