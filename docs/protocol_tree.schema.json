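{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "mrharmony protocol tree document",
  "description": "Per-scanner catalogs of MRI protocols. Reference schema for the format read by mrharmony.io.read_protocol_trees (validation is performed by the reader itself, which reports JSON paths).",
  "type": "object",
  "required": ["scanners"],
  "properties": {
    "scanners": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["scanner_id", "site_id", "protocols"],
        "properties": {
          "scanner_id": {"type": "string"},
          "site_id": {"type": "string"},
          "protocols": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["protocol_name", "body_region", "sequences"],
              "properties": {
                "protocol_name": {"type": "string"},
                "body_region": {"type": "string"},
                "sequences": {
                  "type": "array",
                  "minItems": 1,
                  "items": {"$ref": "#/$defs/sequence"}
                }
              }
            }
          }
        }
      }
    }
  },
  "$defs": {
    "sequence": {
      "type": "object",
      "required": ["raw_name", "tr_ms", "te_ms"],
      "properties": {
        "raw_name": {"type": "string"},
        "tr_ms": {"type": "number", "exclusiveMinimum": 0},
        "te_ms": {"type": "number", "minimum": 0},
        "ti_ms": {
          "type": ["number", "null"],
          "minimum": 0,
          "description": "present implies inversion_recovery true",
          "default": null
        },
        "flip_deg": {"type": "number", "minimum": 0, "maximum": 180, "default": 90},
        "technique": {
          "enum": ["SE", "TSE", "GRE", "EPI", "bSSFP", "UNKNOWN"],
          "default": "UNKNOWN"
        },
        "inversion_recovery": {"type": "boolean", "default": false},
        "orientation": {
          "enum": ["SAG", "COR", "TRA", "OBL", "UNKNOWN"],
          "default": "UNKNOWN"
        },
        "fat_suppression": {"type": "boolean", "default": false},
        "b_values": {
          "type": "array",
          "items": {"type": "number", "minimum": 0},
          "default": []
        },
        "contrast_phase": {"enum": ["NONE", "PRE", "POST"], "default": "NONE"},
        "dimensionality": {"enum": ["2D", "3D"], "default": "2D"},
        "echo_train_length": {"type": "integer", "minimum": 1, "default": 1}
      }
    }
  }
}
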