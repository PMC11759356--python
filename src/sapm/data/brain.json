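{
  "name": "brain",
  "regions": ["AC", "PC", "IC", "HG", "FOrb", "Hippo", "Hypo", "Amyg", "Thal", "NAcc", "VTA", "PAG", "PBN", "LC"],
  "edges": [
    ["AC", "PC"],
    ["IC", "AC"],
    ["AC", "IC"],
    ["Thal", "AC"],
    ["Amyg", "Thal"],
    ["Thal", "PC"],
    ["PC", "AC"],
    ["AC", "FOrb"],
    ["PBN", "Thal"],
    ["Hypo", "PAG"],
    ["Thal", "Hypo"],
    ["Amyg", "Hippo"],
    ["LC", "PBN"],
    ["Hypo", "Thal"],
    ["LC", "Thal"],
    ["AC", "Amyg"],
    ["Thal", "Hippo"],
    ["IC", "HG"],
    ["Hypo", "VTA"],
    ["VTA", "NAcc"],
    ["FOrb", "AC"],
    ["HG", "IC"],
    ["Hippo", "Hypo"],
    ["NAcc", "VTA"],
    ["PAG", "LC"]
  ],
  "latents": [
    {"name": "Lat0", "target": "FOrb"},
    {"name": "Lat1", "target": "IC"},
    {"name": "Lat2", "target": "LC"}
  ]
}
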