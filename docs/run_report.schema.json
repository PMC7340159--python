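{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "dtcprs run report",
  "description": "Machine-readable summary of one processed genome. Deliberately contains no email address, no original filename, and no raw genotype calls, so the report alone cannot be linked back to the submitter.",
  "type": "object",
  "required": [
    "unique_id",
    "source_digest",
    "vendor_dialect",
    "qc",
    "ancestry",
    "scores",
    "tool_version",
    "timestamp"
  ],
  "properties": {
    "unique_id": {
      "type": "string",
      "pattern": "^id_[0-9a-z]{9}$",
      "description": "Anonymous 9-character alphanumeric identifier."
    },
    "source_digest": {
      "type": "string",
      "pattern": "^[0-9a-f]{32}$",
      "description": "md5 of the raw upload bytes; identical files map to one user."
    },
    "vendor_dialect": {
      "type": "string",
      "enum": ["TWENTYTHREE_AND_ME", "ANCESTRY", "MYHERITAGE", "GENERIC"]
    },
    "qc": {
      "type": "object",
      "properties": {
        "call_stats": {"type": "object"},
        "alignment_rejections": {"type": "object"},
        "thresholds": {"type": "object"}
      }
    },
    "ancestry": {
      "type": "object",
      "properties": {
        "label": {"type": ["string", "null"]},
        "margin": {"type": "number"},
        "n_sites": {"type": "integer"}
      }
    },
    "scores": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["trait_id", "z_score", "population", "scaling"],
        "properties": {
          "trait_id": {"type": "string"},
          "raw_sum": {"type": "number"},
          "zero_centered": {"type": "number"},
          "z_score": {"type": "number"},
          "population": {"type": "string"},
          "scaling": {"type": "string"},
          "n_used": {"type": "integer"},
          "n_frequency_filled": {"type": "integer"},
          "n_missing": {"type": "integer"},
          "percentile": {"type": "number"}
        }
      }
    },
    "tool_version": {"type": "string"},
    "timestamp": {"type": "string"}
  },
  "additionalProperties": false
}
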