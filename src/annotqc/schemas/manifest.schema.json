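{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "annotqc study manifest",
  "type": "object",
  "required": ["images", "masks", "rater_tiers", "consensus_raters"],
  "properties": {
    "images": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["image_id", "path", "scale_x_um", "scale_y_um"],
        "properties": {
          "image_id": {"type": "string", "minLength": 1},
          "path": {"type": "string"},
          "scale_x_um": {"type": "number", "exclusiveMinimum": 0},
          "scale_y_um": {"type": "number", "exclusiveMinimum": 0}
        }
      }
    },
    "masks": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["image_id", "rater_id", "round_id", "path"],
        "properties": {
          "image_id": {"type": "string", "minLength": 1},
          "rater_id": {"type": "string", "minLength": 1},
          "round_id": {"type": "integer", "enum": [1, 2]},
          "path": {"type": "string"}
        }
      }
    },
    "rater_tiers": {
      "type": "object",
      "additionalProperties": {"type": "string", "enum": ["expert", "junior"]}
    },
    "consensus_raters": {
      "type": "array",
      "items": {"type": "string", "minLength": 1}
    }
  }
}
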