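{
  "format_version": "1.0",
  "metadata": {
    "title": "Synfire chain with feed-forward inhibition"
  },
  "populations": [
    {
      "id": "fs1",
      "label": {
        "electrophys": "FS",
        "morph": "NPYR"
      },
      "unit": "group1"
    },
    {
      "id": "fs2",
      "label": {
        "electrophys": "FS",
        "morph": "NPYR"
      },
      "unit": "group2"
    },
    {
      "id": "fs3",
      "label": {
        "electrophys": "FS",
        "morph": "NPYR"
      },
      "unit": "group3"
    },
    {
      "id": "rs1",
      "label": {
        "electrophys": "RS",
        "morph": "PYR"
      },
      "unit": "group1"
    },
    {
      "id": "rs2",
      "label": {
        "electrophys": "RS",
        "morph": "PYR"
      },
      "unit": "group2"
    },
    {
      "id": "rs3",
      "label": {
        "electrophys": "RS",
        "morph": "PYR"
      },
      "unit": "group3"
    },
    {
      "id": "stim",
      "label": {
        "morph": "STIM"
      }
    }
  ],
  "projections": [
    {
      "excitation": "excitatory",
      "id": "drive",
      "source": null,
      "target": "stim"
    },
    {
      "excitation": "excitatory",
      "id": "ff_fs1",
      "source": "rs1",
      "target": "fs2"
    },
    {
      "excitation": "excitatory",
      "id": "ff_fs2",
      "source": "rs2",
      "target": "fs3"
    },
    {
      "excitation": "excitatory",
      "id": "ff_rs1",
      "source": "rs1",
      "target": "rs2"
    },
    {
      "excitation": "excitatory",
      "id": "ff_rs2",
      "source": "rs2",
      "target": "rs3"
    },
    {
      "excitation": "inhibitory",
      "id": "ffi1",
      "source": "fs1",
      "target": "rs1"
    },
    {
      "excitation": "inhibitory",
      "id": "ffi2",
      "source": "fs2",
      "target": "rs2"
    },
    {
      "excitation": "inhibitory",
      "id": "ffi3",
      "source": "fs3",
      "target": "rs3"
    },
    {
      "excitation": "excitatory",
      "id": "stim_fs1",
      "source": "stim",
      "target": "fs1"
    },
    {
      "excitation": "excitatory",
      "id": "stim_rs1",
      "source": "stim",
      "target": "rs1"
    }
  ],
  "units": [
    {
      "id": "group1",
      "members": [
        "fs1",
        "rs1"
      ],
      "name": "group"
    },
    {
      "id": "group2",
      "members": [
        "fs2",
        "rs2"
      ],
      "name": "group"
    },
    {
      "id": "group3",
      "members": [
        "fs3",
        "rs3"
      ],
      "name": "group"
    }
  ]
}
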