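{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "bricklab part validation report",
  "type": "object",
  "required": ["parts"],
  "properties": {
    "parts": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["part_id", "ok", "findings"],
        "properties": {
          "part_id": {"type": "string"},
          "ok": {"type": "boolean"},
          "findings": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["code", "severity", "message"],
              "properties": {
                "code": {"type": "string"},
                "severity": {"enum": ["error", "warning", "info"]},
                "message": {"type": "string"},
                "position": {"type": ["integer", "null"]}
              }
            }
          }
        }
      }
    }
  }
}
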