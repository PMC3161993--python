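{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "bricklab RMDI integration report",
  "type": "object",
  "required": ["product_id", "length", "sites", "disrupted", "expressed",
               "reversible"],
  "properties": {
    "product_id": {"type": "string"},
    "length": {"type": "integer", "minimum": 0},
    "sites": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variant", "start", "end", "orientation"],
        "properties": {
          "variant": {"enum": ["loxP", "lox66", "lox71", "loxM"]},
          "start": {"type": "integer"},
          "end": {"type": "integer"},
          "orientation": {"enum": [1, -1]}
        }
      }
    },
    "disrupted": {"type": "array", "items": {"type": "string"}},
    "expressed": {"type": "array", "items": {"type": "string"}},
    "reversible": {"type": "boolean"}
  }
}
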