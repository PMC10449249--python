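{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "AssessmentReportLine",
  "type": "object",
  "required": ["record_id", "total", "level", "flags"],
  "additionalProperties": false,
  "properties": {
    "record_id": {"type": "string"},
    "total": {"type": "integer", "minimum": 0, "maximum": 20},
    "level": {"enum": ["score_zero", "low", "high"]},
    "flags": {"type": "object", "additionalProperties": {"type": "boolean"}},
    "evidence": {"type": "object", "additionalProperties": {"type": "array", "items": {"type": "string"}}}
  }
}
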