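{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "EMRecord",
  "type": "object",
  "required": ["record_id", "record_date"],
  "additionalProperties": false,
  "properties": {
    "record_id": {"type": "string"},
    "record_date": {"type": "string", "format": "date"},
    "diagnoses": {"type": "array", "items": {"type": "string"}},
    "sections": {"type": "object", "additionalProperties": {"type": "string"}},
    "age_years": {"type": ["number", "null"], "minimum": 0},
    "height_m": {"type": ["number", "null"], "exclusiveMinimum": 0},
    "weight_kg": {"type": ["number", "null"], "minimum": 0},
    "labs": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "protein_c": {"type": ["number", "null"], "minimum": 0},
        "protein_s": {"type": ["number", "null"], "minimum": 0},
        "antithrombin_iii": {"type": ["number", "null"], "minimum": 0},
        "d_dimer": {"type": ["number", "null"], "minimum": 0}
      }
    },
    "gold_flags": {
      "type": ["object", "null"],
      "required": ["flags"],
      "properties": {
        "flags": {"type": "object", "additionalProperties": {"type": "boolean"}},
        "provenance": {"type": "object", "additionalProperties": {"type": "array", "items": {"type": "string"}}}
      }
    }
  }
}
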