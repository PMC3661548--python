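{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "morphmix analysis report",
  "type": "object",
  "required": ["input_summary", "descriptive", "warnings", "provenance"],
  "properties": {
    "input_summary": {
      "type": "object",
      "required": ["n_records", "counts", "n_juveniles_excluded"],
      "properties": {
        "n_records": {"type": "integer"},
        "counts": {"type": "object"},
        "n_juveniles_excluded": {"type": "integer"}
      }
    },
    "descriptive": {
      "type": "object",
      "required": ["male", "female"],
      "properties": {
        "male": {"type": "object"},
        "female": {"type": "object"}
      }
    },
    "mixture": {
      "type": ["object", "null"],
      "properties": {
        "weight_homeo": {"type": "number"},
        "homeo": {
          "type": "object",
          "required": ["shape", "scale", "lower_bound"],
          "properties": {
            "shape": {"type": "number"},
            "scale": {"type": "number"},
            "lower_bound": {"type": "number"}
          }
        },
        "hetero": {
          "type": "object",
          "required": ["shape", "scale", "upper_bound"],
          "properties": {
            "shape": {"type": "number"},
            "scale": {"type": "number"},
            "upper_bound": {"type": "number"}
          }
        },
        "n": {"type": ["integer", "null"]},
        "loglik": {"type": ["number", "null"]}
      },
      "required": ["weight_homeo", "homeo", "hetero"]
    },
    "model_comparison": {
      "type": ["object", "null"],
      "properties": {
        "criterion": {"type": "string"},
        "preferred": {"type": ["string", "null"]},
        "candidates": {"type": "array", "items": {"type": "object"}}
      }
    },
    "classification": {
      "type": ["object", "null"],
      "properties": {
        "level": {"type": "number"},
        "rule": {"type": "string"},
        "cutoff_low": {"type": "number"},
        "cutoff_high": {"type": "number"},
        "overlapping": {"type": "boolean"},
        "counts": {"type": "object"},
        "labels": {"type": "array", "items": {"type": "string"}}
      },
      "required": ["level", "rule", "cutoff_low", "cutoff_high", "labels"]
    },
    "allometry": {
      "type": ["object", "null"],
      "properties": {
        "fits": {"type": "object"},
        "comparisons": {"type": "array", "items": {"type": "object"}},
        "warnings": {"type": "array", "items": {"type": "string"}}
      }
    },
    "warnings": {"type": "array", "items": {"type": "string"}},
    "provenance": {
      "type": "object",
      "required": ["software", "version", "config", "config_hash", "seed", "timestamp"],
      "properties": {
        "software": {"type": "string"},
        "version": {"type": "string"},
        "config": {"type": "object"},
        "config_hash": {"type": "string"},
        "seed": {"type": "integer"},
        "timestamp": {"type": "string"}
      }
    }
  }
}
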