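{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "PipelineConfig",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "seed": {"type": "integer"},
    "lexicon_paths": {"type": "object", "additionalProperties": {"type": "string"}},
    "scale_path": {"type": ["string", "null"]},
    "cutoff": {"type": "integer", "minimum": 0},
    "coverage_normalized": {"type": "boolean"},
    "train": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "max_epochs": {"type": "integer", "minimum": 1},
        "patience": {"type": "integer", "minimum": 1},
        "train_fraction": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1},
        "dropout_rate": {"type": "number", "minimum": 0, "maximum": 1},
        "focal_gamma": {"type": "number", "minimum": 0},
        "focal_alpha": {"type": ["array", "null"], "items": {"type": "number"}},
        "seed": {"type": "integer"},
        "mode": {"enum": ["diagnose_only", "diagnose_symptom", "pdcm", "pdcm_without_amplification"]},
        "amplify_fraction": {"type": "number", "minimum": 0, "maximum": 1},
        "uncertainty_markers": {"type": "array", "items": {"type": "string"}},
        "learning_rate": {"type": "number", "exclusiveMinimum": 0},
        "batch_size": {"type": "integer", "minimum": 1},
        "f1_average": {"enum": ["macro", "micro"]},
        "loss_eps": {"type": "number", "exclusiveMinimum": 0}
      }
    },
    "extractor": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "window_days": {"type": "integer", "minimum": 0},
        "negation_window": {"type": ["integer", "null"], "minimum": 0},
        "elderly_age": {"type": "number", "minimum": 0},
        "obesity_bmi": {"type": "number", "minimum": 0},
        "lab_thresholds": {
          "type": "object",
          "additionalProperties": false,
          "properties": {
            "protein_c_low": {"type": "number"},
            "protein_s_low": {"type": "number"},
            "antithrombin_iii_low": {"type": "number"},
            "d_dimer_high": {"type": "number"}
          }
        }
      }
    }
  }
}
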