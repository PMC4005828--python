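{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "inchilink JSON reports",
  "description": "Shapes of the JSON documents the CLI subcommands emit.",
  "$defs": {
    "collisions": {
      "type": "object",
      "required": ["level", "groups", "pair_count", "entries_skipped"],
      "properties": {
        "level": {"enum": ["standard", "extended"]},
        "groups": {
          "type": "array",
          "items": {"type": "array", "items": {"type": "string"},
                    "minItems": 2}
        },
        "pair_count": {"type": "integer", "minimum": 0},
        "entries_skipped": {"type": "integer", "minimum": 0}
      }
    },
    "method_report": {
      "type": "object",
      "required": ["checked", "inconsistent", "not_comparable",
                   "inconsistent_percent"],
      "properties": {
        "checked": {"type": "integer", "minimum": 0},
        "inconsistent": {"type": "integer", "minimum": 0},
        "not_comparable": {"type": "integer", "minimum": 0},
        "inconsistent_percent": {
          "type": ["number", "null"], "minimum": 0, "maximum": 100}
      }
    },
    "check_links": {
      "type": "object",
      "required": ["links", "valid_links", "links_with_inchi", "methods"],
      "properties": {
        "links": {"type": "integer", "minimum": 0},
        "valid_links": {"type": "integer", "minimum": 0},
        "links_with_inchi": {"type": "integer", "minimum": 0},
        "methods": {
          "type": "object",
          "patternProperties": {
            "^(CHSI|CHsI|ChsI|Chs-|Ch-I|C---)/(strict|subset)$": {
              "$ref": "#/$defs/method_report"}
          },
          "additionalProperties": false
        }
      }
    },
    "completeness": {
      "type": "object",
      "required": ["restriction", "manual_links_considered",
                   "found_in_generated", "completeness_percent",
                   "applicable"],
      "properties": {
        "restriction": {"enum": ["same-identifier", "compatible"]},
        "manual_links_considered": {"type": "integer", "minimum": 0},
        "found_in_generated": {"type": "integer", "minimum": 0},
        "completeness_percent": {
          "type": ["number", "null"], "minimum": 0, "maximum": 100},
        "applicable": {"type": "boolean"}
      }
    }
  }
}
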