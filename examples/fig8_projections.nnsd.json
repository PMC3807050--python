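{
  "format_version": "1.0",
  "metadata": {
    "title": "Projection symbol examples"
  },
  "populations": [
    {
      "id": "pyr",
      "label": {
        "electrophys": "RS",
        "morph": "PYR"
      }
    }
  ],
  "projections": [
    {
      "density": 0.5,
      "excitation": "excitatory",
      "id": "in_exc",
      "source": null,
      "target": "pyr"
    },
    {
      "density": 0.1,
      "excitation": "inhibitory",
      "id": "in_inh",
      "source": null,
      "target": "pyr"
    },
    {
      "density": 0.2,
      "excitation": "excitatory",
      "id": "out",
      "source": "pyr",
      "target": null
    },
    {
      "density": 0.2,
      "excitation": "excitatory",
      "id": "self_exc",
      "source": "pyr",
      "target": "pyr"
    }
  ]
}
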