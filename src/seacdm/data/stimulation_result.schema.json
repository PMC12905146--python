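{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "StimulationResult export",
  "type": "object",
  "required": ["criteria", "n_pairs_used", "stimulated_genes"],
  "properties": {
    "criteria": {
      "type": "object",
      "required": ["min_log2_fc", "expr_floor_log2", "min_subjects", "exclude_batch"],
      "properties": {
        "min_log2_fc": {"type": "number", "minimum": 0},
        "expr_floor_log2": {"type": "number"},
        "min_subjects": {"type": "integer", "minimum": 1},
        "exclude_batch": {"type": "boolean"}
      }
    },
    "n_pairs_used": {"type": "integer", "minimum": 0},
    "stimulated_genes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["gene", "n_passing", "mean_delta_log2"],
        "properties": {
          "gene": {"type": "string"},
          "n_passing": {"type": "integer", "minimum": 0},
          "mean_delta_log2": {"type": ["number", "null"]}
        }
      }
    }
  }
}
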