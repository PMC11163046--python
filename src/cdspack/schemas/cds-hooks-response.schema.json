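{
  "$id": "cds-hooks-response",
  "type": "object",
  "required": ["cards"],
  "properties": {
    "cards": {"type": "array", "items": {"$ref": "#/$defs/card"}}
  },
  "$defs": {
    "card": {
      "type": "object",
      "required": ["uuid", "summary", "indicator", "source"],
      "properties": {
        "uuid": {"type": "string", "minLength": 1},
        "summary": {"type": "string", "minLength": 1, "maxLength": 140},
        "detail": {"type": "string"},
        "indicator": {"enum": ["info", "warning", "critical"]},
        "source": {
          "type": "object",
          "required": ["label"],
          "properties": {
            "label": {"type": "string", "minLength": 1},
            "url": {"type": "string"}
          }
        },
        "suggestions": {
          "type": "array",
          "minItems": 1,
          "items": {"$ref": "#/$defs/suggestion"}
        },
        "selectionBehavior": {"enum": ["at-most-one", "any"]}
      }
    },
    "suggestion": {
      "type": "object",
      "required": ["label", "uuid", "actions"],
      "properties": {
        "label": {"type": "string", "minLength": 1},
        "uuid": {"type": "string", "minLength": 1},
        "actions": {
          "type": "array",
          "minItems": 1,
          "items": {"$ref": "#/$defs/action"}
        }
      }
    },
    "action": {
      "type": "object",
      "required": ["type", "description"],
      "properties": {
        "type": {"enum": ["create", "delete", "update"]},
        "description": {"type": "string", "minLength": 1},
        "resource": {
          "type": "object",
          "required": ["resourceType"],
          "properties": {"resourceType": {"type": "string", "minLength": 1}}
        }
      }
    }
  }
}
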