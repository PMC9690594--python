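{
  "seed": 0,
  "group_sizes": {"control": 416, "national": 125, "international": 67},
  "genotype_source": "empirical",
  "enrichment": 1.0,
  "effect_model": {
    "baseline": 199.65,
    "noise_sd": 26.4,
    "shifts": {
      "rs1815739": {"TT": -8.77},
      "rs41274853": {"CC": -11.68}
    }
  }
}
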