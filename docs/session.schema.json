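{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "skelenet session",
  "type": "object",
  "required": ["format", "version", "elements"],
  "properties": {
    "format": {"const": "skelenet-session"},
    "version": {"type": "string", "pattern": "^1\\.[0-9]+$"},
    "metadata": {"type": "object"},
    "elements": {
      "type": "object",
      "required": ["nodes", "edges"],
      "properties": {
        "nodes": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["symbol", "position"],
            "properties": {
              "symbol": {"type": "string", "minLength": 1},
              "level": {"type": ["integer", "string", "null"]},
              "driver_class": {
                "enum": ["SYNDROMIC", "NON_SYNDROMIC", "BOTH", "NONE"]
              },
              "annotations": {
                "type": "object",
                "additionalProperties": {"type": "number"}
              },
              "position": {
                "type": "object",
                "required": ["x", "y"],
                "properties": {
                  "x": {"type": "number"},
                  "y": {"type": "number"}
                }
              }
            }
          }
        },
        "edges": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["src", "dst", "itype"],
            "properties": {
              "src": {"type": "string"},
              "dst": {"type": "string"},
              "itype": {"enum": ["PHYSICAL", "GENETIC", "UNKNOWN"]},
              "evidences": {
                "type": "array",
                "items": {
                  "type": "object",
                  "required": ["source_db", "detail"],
                  "properties": {
                    "source_db": {"enum": ["BIOGRID", "STRING", "PPAXE"]},
                    "detail": {"type": "string"},
                    "reference": {"type": ["string", "null"]},
                    "score": {"type": ["number", "null"]}
                  }
                }
              }
            }
          }
        }
      }
    }
  }
}
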