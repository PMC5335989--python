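{
  "files": {
    "pigments.csv": "db7675d4d365f0012e98eba810df9426fc53a80524b95e9afe266a638b6a7500",
    "quality.csv": "4fe56b7ceb5abe447c1e80eca785bba1ba413d27aa3e03402ecdee8aec3fa252"
  },
  "notes": [
    "Dates carry an assumed year of 2012 (the campaign the printed tables accompany).",
    "Empty cells are missing values: 'n.d.' entries and the shorter covered series' blank trailing dates; never zero.",
    "Firmness 100 is the penetrometer ceiling (flagged via firmness_at_ceiling), printed without an SD.",
    "Chl b for Bellise without cover was printed with a truncated unit (nmol*g^-); transcribed as nmol*g^-1, assuming a typographic slip."
  ]
}
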