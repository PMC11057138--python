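{
  "description": "Structured result of one pipeline run (JSON-serializable, no timestamps).",
  "properties": {
    "attribute_tables": {
      "additionalProperties": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Attribute Tables",
      "type": "object"
    },
    "brokers": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Brokers",
      "type": "array"
    },
    "centrality": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Centrality",
      "type": "array"
    },
    "characteristics": {
      "additionalProperties": true,
      "title": "Characteristics",
      "type": "object"
    },
    "characteristics_full": {
      "additionalProperties": true,
      "title": "Characteristics Full",
      "type": "object"
    },
    "components": {
      "additionalProperties": true,
      "title": "Components",
      "type": "object"
    },
    "key_policymakers": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Key Policymakers",
      "type": "array"
    },
    "organizations": {
      "additionalProperties": {
        "items": {
          "additionalProperties": true,
          "type": "object"
        },
        "type": "array"
      },
      "title": "Organizations",
      "type": "object"
    },
    "provenance": {
      "additionalProperties": true,
      "title": "Provenance",
      "type": "object"
    }
  },
  "required": [
    "characteristics",
    "characteristics_full",
    "components",
    "centrality",
    "brokers",
    "key_policymakers",
    "organizations",
    "attribute_tables",
    "provenance"
  ],
  "title": "AnalysisReport",
  "type": "object"
}
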