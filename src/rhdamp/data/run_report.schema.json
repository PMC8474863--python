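{
  "type": "object",
  "required": ["schema_version", "ratios", "error_ratios", "dedup", "ledger", "qc_flags"],
  "properties": {
    "schema_version": {"type": "integer"},
    "ratios": {
      "type": "object",
      "required": ["box", "exon9"],
      "properties": {
        "box": {
          "type": "object",
          "required": ["classes", "counts", "percent"],
          "properties": {
            "classes": {"type": "array", "items": {"type": "string"}},
            "counts": {"type": "array", "items": {"type": "integer"}},
            "percent": {"type": ["array", "null"], "items": {"type": "string"}}
          }
        },
        "exon9": {
          "type": "object",
          "required": ["classes", "counts", "percent"],
          "properties": {
            "classes": {"type": "array", "items": {"type": "string"}},
            "counts": {"type": "array", "items": {"type": "integer"}},
            "percent": {"type": ["array", "null"], "items": {"type": "string"}}
          }
        }
      }
    },
    "error_ratios": {"type": "object"},
    "dedup": {
      "type": ["object", "null"],
      "required": ["input_reads", "unique_molecules", "unique_umis", "duplicates_removed"],
      "properties": {
        "input_reads": {"type": "integer"},
        "unique_molecules": {"type": "integer"},
        "unique_umis": {"type": "integer"},
        "duplicates_removed": {"type": "integer"}
      }
    },
    "ledger": {"type": ["object", "null"]},
    "qc_flags": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["flag", "group", "class", "ratio", "background_max"],
        "properties": {
          "flag": {"type": "string"},
          "group": {"type": "string"},
          "class": {"type": "string"},
          "ratio": {"type": "number"},
          "background_max": {"type": "number"}
        }
      }
    }
  }
}
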