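{
  "$comment": "Contract for rulebase YAML documents. The parser in pedcds.knowledge enforces these constraints in code; this document records them for rulebase authors.",
  "type": "object",
  "required": ["meta", "data_elements", "recommendations", "rules"],
  "properties": {
    "meta": {
      "type": "object",
      "required": ["name", "age_coverage_months"],
      "properties": {
        "name": {"type": "string"},
        "version": {"type": "integer"},
        "age_coverage_months": {
          "type": "array", "items": {"type": "number"},
          "minItems": 2, "maxItems": 2,
          "$comment": "half-open [lower, upper) in months"
        },
        "provenance": {"type": "string"}
      }
    },
    "thresholds": {
      "type": "object",
      "additionalProperties": {"type": "number"}
    },
    "lipid_cutpoints": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "properties": {
          "direction": {"enum": ["high_is_bad", "low_is_bad"]},
          "bands": {"$ref": "#/$defs/bands"},
          "by_age": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["age_band", "bands"],
              "properties": {
                "age_band": {"type": "array", "minItems": 2, "maxItems": 2},
                "bands": {"$ref": "#/$defs/bands"}
              }
            }
          }
        }
      }
    },
    "data_elements": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "kind"],
        "properties": {
          "id": {"type": "string"},
          "kind": {"enum": ["numeric", "enumerated", "tri_state", "date"]},
          "units": {"type": "string"},
          "allowed": {"type": "array", "items": {"type": "string"}}
        },
        "$comment": "enumerated elements require 'allowed'; tri_state implies [yes, no, unknown]"
      }
    },
    "supportive_actions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "text"],
        "properties": {"id": {"type": "string"}, "text": {"type": "string", "minLength": 1}}
      }
    },
    "recommendations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "text"],
        "properties": {"id": {"type": "string"}, "text": {"type": "string", "minLength": 1}}
      }
    },
    "rules": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "domain", "age_band", "trigger", "recommendation", "grade"],
        "properties": {
          "id": {"type": "string"},
          "domain": {
            "enum": ["family_history", "nutrition_diet", "physical_activity",
                     "tobacco_exposure", "lipids", "overweight_obesity",
                     "blood_pressure", "other_risk_condition"]
          },
          "age_band": {
            "type": "array", "items": {"type": "number"},
            "minItems": 2, "maxItems": 2,
            "$comment": "half-open [lower, upper) in months; lower < upper"
          },
          "trigger": {"$ref": "#/$defs/trigger"},
          "recommendation": {"type": "string", "$comment": "must resolve in recommendations"},
          "grade": {"enum": ["A", "B", "C", "D", "E", "F"]},
          "actions": {
            "type": "array", "items": {"type": "string"},
            "$comment": "each must resolve in supportive_actions"
          }
        }
      }
    }
  },
  "$defs": {
    "bands": {
      "type": "array",
      "items": {
        "type": "array", "minItems": 2, "maxItems": 2,
        "$comment": "[label, upper_bound]; last band's bound is null (unbounded)"
      }
    },
    "trigger": {
      "oneOf": [
        {
          "type": "object",
          "required": ["all"],
          "properties": {"all": {"type": "array", "items": {"$ref": "#/$defs/trigger"}, "minItems": 1}}
        },
        {
          "type": "object",
          "required": ["any"],
          "properties": {"any": {"type": "array", "items": {"$ref": "#/$defs/trigger"}, "minItems": 1}}
        },
        {
          "type": "object",
          "required": ["var", "op"],
          "properties": {
            "var": {"type": "string", "$comment": "must be a declared data element"},
            "op": {"enum": ["eq", "ne", "lt", "le", "gt", "ge", "in_set", "is_unknown"]},
            "value": {
              "$comment": "numeric for lt/le/gt/ge; list for in_set; absent for is_unknown; numeric comparators only on numeric variables"
            }
          }
        }
      ]
    }
  }
}
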