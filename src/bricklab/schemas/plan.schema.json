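{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "bricklab assembly plan",
  "type": "object",
  "required": ["design", "n_rounds", "rounds", "warnings"],
  "properties": {
    "design": {"type": "array", "items": {"type": "string"}},
    "n_rounds": {"type": "integer", "minimum": 0},
    "rounds": {
      "type": "object",
      "additionalProperties": {
        "type": "array",
        "items": {
          "type": "object",
          "required": ["name", "left", "right", "round"],
          "properties": {
            "name": {"type": "string"},
            "left": {"type": "string"},
            "right": {"type": "string"},
            "backbone": {"type": ["string", "null"]},
            "antibiotic": {"type": ["string", "null"]},
            "round": {"type": "integer", "minimum": 1}
          }
        }
      }
    },
    "warnings": {"type": "array", "items": {"type": "string"}},
    "seed": {"type": ["integer", "null"]}
  }
}
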