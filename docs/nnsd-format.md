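# NNSD file format

NNSD (`.nnsd.json`, UTF-8 JSON) is the textual serialization of a neural
schematic model. One JSON object with the following sections; all element
lists are sorted by id on write, keys are sorted, and output ends in a
newline, so serialization is byte-deterministic.

```json
{
  "format_version": "1.0",
  "metadata": { "title": "..." },
  "populations": [
    {
      "id": "pyr",
      "label": { "electrophys": "RS", "morph": "PYR" },
      "layer": "VI",
      "region": "area5",
      "unit": "col1",
      "attributes": { "size": 400 }
    }
  ],
  "projections": [
    {
      "id": "in_exc",
      "source": null,
      "target": "pyr",
      "excitation": "excitatory",
      "density": 0.5,
      "attributes": {}
    }
  ],
  "layers":  [ { "area": "area5", "name": "VI" } ],
  "regions": [ { "id": "area5", "kind": "area", "name": "Area 5", "display_order": 1 } ],
  "units":   [ { "id": "col1", "name": "column", "members": ["pyr"] } ]
}
```

Field notes:

* `format_version` — required, currently `"1.0"`.
* `label` — at least one of `electrophys` (normal typeset) and `morph`
  (italic typeset); tokens are uppercase alphanumeric.
* `source` / `target` — population id, or `null` for an external endpoint
  (input when the source is null, output when the target is null; never
  both). The id `"EXTERNAL"` is reserved and rejected for populations.
* `density` — relative connection density in [0, 1]. Alternatively
  `density_percent` may be given and is divided by 100 on read.
* `layer` — roman numeral `I`..`VI`; requires `region` to name an area
  that declares that layer. `kind` is `"area"` or `"ncr"`; NCRs must not
  contain layers.
* `units[].members` — population ids and/or sub-unit ids; membership must
  form a forest and each population may appear in at most one unit.
* `attributes` — open key→value map, carried but never rendered. Unknown
  keys found directly on an element are folded into `attributes` on read
  instead of being dropped.

Reading validates against the full notation rulebook and reports
violations as diagnostics naming the rule (e.g. `R-NCR-NOLAYERS`);
writing refuses a model that has ERROR diagnostics.
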