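{
  "type": "object",
  "required": [
    "version",
    "seed",
    "config",
    "normalization",
    "differential_expression",
    "profiles",
    "sample_clusters",
    "enrichment",
    "ploidy",
    "bacteroids",
    "classification"
  ],
  "properties": {
    "version": {"type": "string"},
    "seed": {"type": "integer"},
    "config": {"type": "object"},
    "normalization": {
      "type": "object",
      "required": ["n_arrays", "n_invariant", "median_identity_max_deviation"],
      "properties": {
        "n_arrays": {"type": "integer"},
        "n_invariant": {"type": "integer"},
        "median_identity_max_deviation": {"type": "number"}
      }
    },
    "differential_expression": {
      "type": "object",
      "required": ["alpha", "n_selected"],
      "properties": {
        "alpha": {"type": "number"},
        "n_selected": {"type": "integer"}
      }
    },
    "profiles": {
      "type": "object",
      "required": ["k", "sizes"],
      "properties": {"k": {"type": "integer"}, "sizes": {"type": "object"}}
    },
    "sample_clusters": {
      "type": "object",
      "required": ["k", "labels"],
      "properties": {"k": {"type": "integer"}, "labels": {"type": "object"}}
    },
    "enrichment": {"type": "object"},
    "ploidy": {"type": "object"},
    "bacteroids": {"type": "object"},
    "classification": {
      "type": "object",
      "required": ["categories", "n_distinct_mutant_categories"],
      "properties": {
        "categories": {"type": "object"},
        "n_distinct_mutant_categories": {"type": "integer"}
      }
    },
    "qpcr": {"type": "object"}
  }
}
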