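{
  "$id": "cds-hooks-discovery",
  "type": "object",
  "required": ["services"],
  "properties": {
    "services": {"type": "array", "items": {"$ref": "#/$defs/service"}}
  },
  "$defs": {
    "service": {
      "type": "object",
      "required": ["id", "hook", "description"],
      "properties": {
        "id": {"type": "string", "minLength": 1},
        "hook": {"type": "string", "minLength": 1},
        "title": {"type": "string"},
        "description": {"type": "string", "minLength": 1},
        "prefetch": {"type": "object"}
      }
    }
  }
}
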