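{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "mosquitodyn JSON reports",
  "description": "Structure of the JSON reports written by the r0, orbit and check subcommands.",
  "type": "object",
  "required": ["tool", "version"],
  "properties": {
    "tool": {"const": "mosquitodyn"},
    "version": {"type": "string"},
    "config": {"type": "string"},
    "seed": {"type": "integer"},
    "rho_FV": {"type": "number"},
    "classification": {"enum": ["below_one", "at_one", "above_one"]},
    "R0": {"type": "number", "minimum": 0},
    "bracket": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2},
    "tolerance": {"type": "number", "exclusiveMinimum": 0},
    "fixed_point": {"type": "array", "items": {"type": "number", "minimum": 0}},
    "residual": {"type": "number", "minimum": 0},
    "multipliers": {"type": "array"},
    "multiplier_moduli": {"type": "array", "items": {"type": "number", "minimum": 0}},
    "stability": {"enum": ["attracting", "saddle", "repelling", "marginal"]},
    "converged": {"type": "boolean"},
    "iterations": {"type": "integer", "minimum": 0},
    "zero_linkage_bE": {"$ref": "#/$defs/condition"},
    "zero_linkage_h": {"$ref": "#/$defs/condition"},
    "gap_condition": {"$ref": "#/$defs/condition"},
    "mortality_budget": {"$ref": "#/$defs/condition"},
    "mortality_floor_average": {"$ref": "#/$defs/condition"},
    "dissipativity": {
      "type": "object",
      "required": ["U_M", "K_bound"],
      "properties": {
        "U_M": {"type": "number", "minimum": 0},
        "K_bound": {"type": "number", "exclusiveMinimum": 0}
      }
    }
  },
  "$defs": {
    "condition": {
      "type": "object",
      "required": ["holds", "margin"],
      "properties": {
        "holds": {"type": "boolean"},
        "margin": {"type": "number"},
        "witnesses": {"type": "array", "items": {"type": "number"}},
        "detail": {"type": "object"}
      }
    }
  }
}
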