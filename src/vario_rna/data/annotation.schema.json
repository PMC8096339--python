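{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "vario-rna annotation output",
  "type": "object",
  "required": ["options", "records"],
  "properties": {
    "options": {
      "type": "object",
      "required": ["format", "strict"],
      "properties": {
        "format": {"type": "string", "enum": ["json"]},
        "strict": {"type": "boolean"}
      }
    },
    "records": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variant", "terms", "warnings"],
        "properties": {
          "variant": {"type": "string"},
          "transcript_id": {"type": ["string", "null"]},
          "terms": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["accession", "name", "basis"],
              "properties": {
                "accession": {"type": "string", "pattern": "^VariO:[0-9]{4}$"},
                "name": {"type": "string", "minLength": 1},
                "basis": {"type": "string", "enum": ["rule", "metadata"]}
              }
            }
          },
          "coding_effect": {"type": ["string", "null"]},
          "warnings": {"type": "array", "items": {"type": "string"}},
          "error": {"type": ["string", "null"]}
        }
      }
    }
  }
}
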