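{
  "name": "brainstem_cord",
  "regions": ["Thal", "Hypo", "PAG", "LC", "PBN", "NTS", "NGc", "NRM", "DRt", "C6RD"],
  "edges": [
    ["LC", "Thal"],
    ["LC", "PBN"],
    ["NRM", "C6RD"],
    ["Hypo", "NTS"],
    ["PBN", "Thal"],
    ["Hypo", "Thal"],
    ["Hypo", "PAG"],
    ["Thal", "Hypo"],
    ["PAG", "NRM"],
    ["PAG", "NGc"],
    ["C6RD", "DRt"],
    ["NTS", "LC"],
    ["NGc", "C6RD"],
    ["DRt", "C6RD"]
  ],
  "latents": [
    {"name": "Lat0", "target": "LC"}
  ]
}
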