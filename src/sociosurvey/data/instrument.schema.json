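{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/sociosurvey/instrument.schema.json",
  "title": "Instrument definition dialect",
  "description": "A validated questionnaire instrument: ordered multiple-choice items, an arithmetic scoring rule over item values, optional qualitative score bands covering the attainable score range exactly, and optional subscales.",
  "type": "object",
  "required": ["id", "name", "citation", "items"],
  "properties": {
    "id": {"type": "string", "minLength": 1},
    "name": {"type": "string", "minLength": 1},
    "citation": {
      "type": "string",
      "minLength": 1,
      "description": "Reference where the complete description of the questionnaire is stated (required)."
    },
    "items": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["id", "options"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "text": {"type": "string"},
          "options": {
            "type": "array",
            "minItems": 2,
            "items": {
              "type": "object",
              "required": ["code", "value"],
              "properties": {
                "code": {"type": "string"},
                "label": {"type": "string"},
                "value": {"type": "number"}
              }
            }
          }
        }
      }
    },
    "scoring": {
      "type": "object",
      "properties": {
        "expression": {
          "type": "string",
          "description": "Arithmetic expression over item ids using + - * /, sum(...), mean(...), literals; sum(*) means the sum of all item values (the default)."
        }
      }
    },
    "bands": {
      "type": "array",
      "description": "Quantitative-to-qualitative mapping; sorted, non-overlapping, adjacent (next.lo = prev.hi + 1 on integer scales), jointly covering the attainable range exactly.",
      "items": {
        "type": "object",
        "required": ["label", "lo", "hi"],
        "properties": {
          "label": {"type": "string"},
          "action": {"type": "string", "description": "Recommended intervention text."},
          "lo": {"type": "number"},
          "hi": {"type": "number"}
        }
      }
    },
    "subscales": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "item_ids"],
        "properties": {
          "name": {"type": "string"},
          "item_ids": {"type": "array", "minItems": 1, "items": {"type": "string"}},
          "scoring": {"type": "string"}
        }
      }
    },
    "provisional": {
      "type": "boolean",
      "description": "True when item wording or option values are placeholders pending the instrument's normative documentation."
    }
  }
}
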