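{
  "format_version": "1.0",
  "layers": [
    {
      "area": "cortex",
      "name": "II"
    },
    {
      "area": "cortex",
      "name": "III"
    }
  ],
  "metadata": {
    "title": "Associative memory hypercolumn"
  },
  "populations": [
    {
      "id": "basket",
      "label": {
        "electrophys": "FS",
        "morph": "NPYR"
      },
      "layer": "III",
      "region": "cortex",
      "unit": "hypercolumn"
    },
    {
      "id": "m1_pyr",
      "label": {
        "electrophys": "RS",
        "morph": "PYR"
      },
      "layer": "III",
      "region": "cortex",
      "unit": "m1"
    },
    {
      "id": "m1_rsnp",
      "label": {
        "electrophys": "RS",
        "morph": "NPYR"
      },
      "layer": "II",
      "region": "cortex",
      "unit": "m1"
    },
    {
      "id": "m2_pyr",
      "label": {
        "electrophys": "RS",
        "morph": "PYR"
      },
      "layer": "III",
      "region": "cortex",
      "unit": "m2"
    },
    {
      "id": "m2_rsnp",
      "label": {
        "electrophys": "RS",
        "morph": "NPYR"
      },
      "layer": "II",
      "region": "cortex",
      "unit": "m2"
    },
    {
      "id": "stim",
      "label": {
        "morph": "STIM"
      },
      "region": "cortex"
    }
  ],
  "projections": [
    {
      "excitation": "inhibitory",
      "id": "basket_m1",
      "source": "basket",
      "target": "m1_pyr"
    },
    {
      "excitation": "inhibitory",
      "id": "basket_m2",
      "source": "basket",
      "target": "m2_pyr"
    },
    {
      "excitation": "excitatory",
      "id": "drive",
      "source": null,
      "target": "stim"
    },
    {
      "excitation": "excitatory",
      "id": "m1_pyr_basket",
      "source": "m1_pyr",
      "target": "basket"
    },
    {
      "excitation": "excitatory",
      "id": "m1_pyr_m2_rsnp",
      "source": "m1_pyr",
      "target": "m2_rsnp"
    },
    {
      "excitation": "excitatory",
      "id": "m1_recur",
      "source": "m1_pyr",
      "target": "m1_pyr"
    },
    {
      "excitation": "inhibitory",
      "id": "m1_rsnp_pyr",
      "source": "m1_rsnp",
      "target": "m1_pyr"
    },
    {
      "excitation": "excitatory",
      "id": "m2_pyr_basket",
      "source": "m2_pyr",
      "target": "basket"
    },
    {
      "excitation": "excitatory",
      "id": "m2_pyr_m1_rsnp",
      "source": "m2_pyr",
      "target": "m1_rsnp"
    },
    {
      "excitation": "excitatory",
      "id": "m2_recur",
      "source": "m2_pyr",
      "target": "m2_pyr"
    },
    {
      "excitation": "inhibitory",
      "id": "m2_rsnp_pyr",
      "source": "m2_rsnp",
      "target": "m2_pyr"
    },
    {
      "excitation": "excitatory",
      "id": "stim_m1",
      "source": "stim",
      "target": "m1_pyr"
    },
    {
      "excitation": "excitatory",
      "id": "stim_m2",
      "source": "stim",
      "target": "m2_pyr"
    }
  ],
  "regions": [
    {
      "display_order": 0,
      "id": "cortex",
      "kind": "area",
      "name": ""
    }
  ],
  "units": [
    {
      "id": "hypercolumn",
      "members": [
        "basket",
        "m1",
        "m2"
      ],
      "name": "Hypercolumn"
    },
    {
      "id": "m1",
      "members": [
        "m1_pyr",
        "m1_rsnp"
      ],
      "name": "Minicolumn"
    },
    {
      "id": "m2",
      "members": [
        "m2_pyr",
        "m2_rsnp"
      ],
      "name": "Minicolumn"
    }
  ]
}
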