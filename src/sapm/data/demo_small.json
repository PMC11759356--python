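{
  "name": "demo_small",
  "regions": ["A", "B", "C", "D", "E"],
  "edges": [
    ["A", "B"],
    ["A", "C"],
    ["B", "C"],
    ["B", "E"],
    ["C", "D"],
    ["D", "E"],
    ["E", "A"]
  ],
  "latents": [
    {"name": "L0", "target": "A"}
  ]
}
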