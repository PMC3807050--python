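{
  "format_version": "1.0",
  "layers": [
    {
      "area": "area5",
      "name": "VI"
    }
  ],
  "metadata": {
    "title": "Thalamocortical regions"
  },
  "populations": [
    {
      "id": "npyr",
      "label": {
        "electrophys": "FS",
        "morph": "NPYR"
      },
      "layer": "VI",
      "region": "area5"
    },
    {
      "id": "pyr",
      "label": {
        "electrophys": "RS",
        "morph": "PYR"
      },
      "layer": "VI",
      "region": "area5"
    },
    {
      "id": "re",
      "label": {
        "morph": "RE"
      },
      "region": "thalamus"
    },
    {
      "id": "tc",
      "label": {
        "morph": "TC"
      },
      "region": "thalamus"
    }
  ],
  "projections": [
    {
      "excitation": "inhibitory",
      "id": "npyr_pyr",
      "source": "npyr",
      "target": "pyr"
    },
    {
      "excitation": "excitatory",
      "id": "pyr_npyr",
      "source": "pyr",
      "target": "npyr"
    },
    {
      "excitation": "excitatory",
      "id": "pyr_pyr",
      "source": "pyr",
      "target": "pyr"
    },
    {
      "excitation": "excitatory",
      "id": "pyr_re",
      "source": "pyr",
      "target": "re"
    },
    {
      "excitation": "excitatory",
      "id": "pyr_tc",
      "source": "pyr",
      "target": "tc"
    },
    {
      "excitation": "inhibitory",
      "id": "re_re",
      "source": "re",
      "target": "re"
    },
    {
      "excitation": "inhibitory",
      "id": "re_tc",
      "source": "re",
      "target": "tc"
    },
    {
      "excitation": "excitatory",
      "id": "stim_pyr",
      "source": null,
      "target": "pyr"
    },
    {
      "excitation": "excitatory",
      "id": "stim_tc",
      "source": null,
      "target": "tc"
    },
    {
      "excitation": "excitatory",
      "id": "tc_npyr",
      "source": "tc",
      "target": "npyr"
    },
    {
      "excitation": "excitatory",
      "id": "tc_pyr",
      "source": "tc",
      "target": "pyr"
    },
    {
      "excitation": "excitatory",
      "id": "tc_re",
      "source": "tc",
      "target": "re"
    }
  ],
  "regions": [
    {
      "display_order": 0,
      "id": "thalamus",
      "kind": "ncr",
      "name": "Thalamus"
    },
    {
      "display_order": 1,
      "id": "area5",
      "kind": "area",
      "name": "Area 5"
    }
  ]
}
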