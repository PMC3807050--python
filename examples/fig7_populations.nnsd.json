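{
  "format_version": "1.0",
  "metadata": {
    "title": "Population symbol examples"
  },
  "populations": [
    {
      "id": "pois",
      "label": {
        "electrophys": "POIS"
      }
    },
    {
      "id": "pyr",
      "label": {
        "electrophys": "RS",
        "morph": "PYR"
      }
    },
    {
      "id": "uni",
      "label": {
        "morph": "UNI"
      }
    }
  ]
}
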