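{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Linkage-group view (before/after states of one linkage group)",
  "type": "object",
  "required": ["linkage_group", "state", "nodes", "scaffolds", "links"],
  "properties": {
    "linkage_group": {"type": "string"},
    "state": {"enum": ["before", "after"]},
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["cm"],
        "properties": {"cm": {"type": "number"}}
      }
    },
    "scaffolds": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "len", "placement", "orientation", "evidence"],
        "properties": {
          "id": {"type": "string"},
          "len": {"type": ["integer", "null"]},
          "placement": {
            "type": ["integer", "null"],
            "description": "rank within the chromosome, null before integration"
          },
          "orientation": {"enum": ["+", "-", "?"]},
          "evidence": {"enum": ["map", "synteny", "fallback", "input"]}
        }
      }
    },
    "links": {
      "type": "array",
      "description": "one entry per marker joining a map position to an alignment",
      "items": {
        "type": "object",
        "required": ["marker", "cm", "bp", "status"],
        "properties": {
          "marker": {"type": "string"},
          "cm": {"type": "number"},
          "bp": {"type": "integer"},
          "status": {"type": "string"}
        }
      }
    }
  }
}
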