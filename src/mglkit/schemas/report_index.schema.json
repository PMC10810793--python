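{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "mglkit report index",
  "type": "object",
  "required": ["summaries"],
  "properties": {
    "summaries": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "path", "n_rows", "description"],
        "properties": {
          "name": {"type": "string"},
          "path": {"type": "string"},
          "n_rows": {"type": "integer", "minimum": 0},
          "description": {"type": "string"}
        }
      }
    }
  }
}
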