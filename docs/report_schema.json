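{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "bfcheck check report",
  "type": "object",
  "required": [
    "specific_label", "general_label", "m", "seed", "observed_bf",
    "theorem1", "theorem2", "universal_bound", "woe", "batches"
  ],
  "properties": {
    "specific_label": {"type": "string"},
    "general_label": {"type": "string"},
    "m": {"type": "integer", "minimum": 2},
    "seed": {"type": "integer"},
    "observed_bf": {"type": ["number", "null"]},
    "theorem1": {
      "type": "object",
      "required": ["mean", "mc_se", "m_used", "tolerance_multiplier", "verdict", "heavy_tail_caution", "skewness"],
      "properties": {
        "mean": {"type": "number"},
        "mc_se": {"type": "number"},
        "m_used": {"type": "integer"},
        "tolerance_multiplier": {"type": "number"},
        "verdict": {"enum": ["pass", "fail"]},
        "heavy_tail_caution": {"type": "boolean"},
        "skewness": {"type": "number"}
      }
    },
    "theorem2": {
      "type": ["object", "null"],
      "required": ["order_low", "moment_specific_true", "moment_general_true", "relative_difference", "combined_mc_se", "tolerance_multiplier", "verdict"],
      "properties": {
        "order_low": {"type": "integer"},
        "moment_specific_true": {"$ref": "#/$defs/moment"},
        "moment_general_true": {"$ref": "#/$defs/moment"},
        "relative_difference": {"type": "number"},
        "combined_mc_se": {"type": "number"},
        "tolerance_multiplier": {"type": "number"},
        "verdict": {"enum": ["pass", "fail"]}
      }
    },
    "universal_bound": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["alpha", "threshold", "empirical_fraction", "bound_satisfied"],
        "properties": {
          "alpha": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
          "threshold": {"type": "number"},
          "empirical_fraction": {"type": "number", "minimum": 0, "maximum": 1},
          "bound_satisfied": {"type": "boolean"}
        }
      }
    },
    "woe": {
      "type": "object",
      "required": ["mean_log_bf", "sd_log_bf", "skewness_bf"],
      "properties": {
        "mean_log_bf": {"type": "number"},
        "sd_log_bf": {"type": "number"},
        "skewness_bf": {"type": "number"}
      }
    },
    "batches": {
      "type": "object",
      "required": ["general_true", "specific_true"],
      "additionalProperties": {"type": ["object", "null"]}
    }
  },
  "$defs": {
    "moment": {
      "type": "object",
      "required": ["order", "estimate", "mc_se", "m_used"],
      "properties": {
        "order": {"type": "integer"},
        "estimate": {"type": "number"},
        "mc_se": {"type": "number"},
        "m_used": {"type": "integer"}
      }
    }
  }
}
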