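{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "oppmcda criteria configuration",
  "type": "object",
  "required": ["criteria"],
  "properties": {
    "criteria": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["id", "name"],
        "properties": {
          "id": {"type": "string", "minLength": 1, "pattern": "^[a-z][a-z0-9_]*$"},
          "name": {"type": "string", "minLength": 1},
          "rank": {"type": "integer", "minimum": 1},
          "description": {"type": "string"},
          "scale": {
            "oneOf": [
              {"const": "price_rule"},
              {
                "type": "array",
                "minItems": 2,
                "items": {
                  "type": "object",
                  "required": ["label", "value"],
                  "properties": {
                    "label": {"type": "string", "minLength": 1},
                    "value": {"type": "number", "minimum": 0, "maximum": 1}
                  }
                }
              }
            ]
          }
        }
      }
    }
  }
}
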