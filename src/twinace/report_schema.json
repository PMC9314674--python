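{
  "$defs": {
    "ComponentsEntry": {
      "properties": {
        "a": {
          "title": "A",
          "type": "number"
        },
        "age": {
          "title": "Age",
          "type": "integer"
        },
        "c": {
          "title": "C",
          "type": "number"
        },
        "e": {
          "title": "E",
          "type": "number"
        },
        "prs": {
          "default": 0.0,
          "title": "Prs",
          "type": "number"
        }
      },
      "required": [
        "age",
        "a",
        "c",
        "e"
      ],
      "title": "ComponentsEntry",
      "type": "object"
    },
    "FitEntry": {
      "properties": {
        "components": {
          "items": {
            "$ref": "#/$defs/ComponentsEntry"
          },
          "title": "Components",
          "type": "array"
        },
        "converged": {
          "title": "Converged",
          "type": "boolean"
        },
        "grad_norm": {
          "title": "Grad Norm",
          "type": "number"
        },
        "loglik": {
          "title": "Loglik",
          "type": "number"
        },
        "model_name": {
          "title": "Model Name",
          "type": "string"
        },
        "n_dropped": {
          "title": "N Dropped",
          "type": "integer"
        },
        "n_free": {
          "title": "N Free",
          "type": "integer"
        },
        "n_pairs": {
          "title": "N Pairs",
          "type": "integer"
        },
        "params": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Params",
          "type": "object"
        },
        "stability": {
          "anyOf": [
            {
              "$ref": "#/$defs/StabilityEntry"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        }
      },
      "required": [
        "model_name",
        "loglik",
        "n_free",
        "converged",
        "grad_norm",
        "params",
        "components",
        "n_pairs",
        "n_dropped"
      ],
      "title": "FitEntry",
      "type": "object"
    },
    "RunMeta": {
      "properties": {
        "config": {
          "additionalProperties": true,
          "title": "Config",
          "type": "object"
        },
        "config_hash": {
          "title": "Config Hash",
          "type": "string"
        },
        "package_version": {
          "title": "Package Version",
          "type": "string"
        },
        "seed": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Seed"
        }
      },
      "required": [
        "package_version",
        "config",
        "config_hash"
      ],
      "title": "RunMeta",
      "type": "object"
    },
    "StabilityEntry": {
      "properties": {
        "contribution_a": {
          "title": "Contribution A",
          "type": "number"
        },
        "contribution_c": {
          "title": "Contribution C",
          "type": "number"
        },
        "contribution_e": {
          "title": "Contribution E",
          "type": "number"
        },
        "contribution_prs": {
          "title": "Contribution Prs",
          "type": "number"
        },
        "proportion_a": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Proportion A"
        },
        "proportion_c": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Proportion C"
        },
        "proportion_e": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Proportion E"
        },
        "proportion_prs": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Proportion Prs"
        },
        "r_a": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "R A"
        },
        "r_e": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "R E"
        },
        "r_liability": {
          "title": "R Liability",
          "type": "number"
        }
      },
      "required": [
        "contribution_a",
        "contribution_c",
        "contribution_e",
        "contribution_prs",
        "r_liability"
      ],
      "title": "StabilityEntry",
      "type": "object"
    },
    "TestEntry": {
      "properties": {
        "boundary": {
          "default": false,
          "title": "Boundary",
          "type": "boolean"
        },
        "df": {
          "title": "Df",
          "type": "integer"
        },
        "name": {
          "title": "Name",
          "type": "string"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        },
        "p_value_mixture": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "P Value Mixture"
        },
        "statistic": {
          "title": "Statistic",
          "type": "number"
        }
      },
      "required": [
        "name",
        "statistic",
        "df",
        "p_value"
      ],
      "title": "TestEntry",
      "type": "object"
    },
    "TetrachoricEntry": {
      "properties": {
        "age": {
          "title": "Age",
          "type": "integer"
        },
        "boundary": {
          "default": false,
          "title": "Boundary",
          "type": "boolean"
        },
        "group": {
          "title": "Group",
          "type": "string"
        },
        "n_pairs": {
          "title": "N Pairs",
          "type": "integer"
        },
        "rho": {
          "title": "Rho",
          "type": "number"
        },
        "se": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Se"
        }
      },
      "required": [
        "group",
        "age",
        "rho",
        "n_pairs"
      ],
      "title": "TetrachoricEntry",
      "type": "object"
    }
  },
  "description": "Machine-readable analysis output; every number is recomputable from\nthe serialized fit entries.",
  "properties": {
    "fits": {
      "items": {
        "$ref": "#/$defs/FitEntry"
      },
      "title": "Fits",
      "type": "array"
    },
    "meta": {
      "$ref": "#/$defs/RunMeta"
    },
    "tests": {
      "items": {
        "$ref": "#/$defs/TestEntry"
      },
      "title": "Tests",
      "type": "array"
    },
    "tetrachoric": {
      "items": {
        "$ref": "#/$defs/TetrachoricEntry"
      },
      "title": "Tetrachoric",
      "type": "array"
    }
  },
  "required": [
    "meta",
    "tetrachoric",
    "fits",
    "tests"
  ],
  "title": "AnalysisReport",
  "type": "object"
}
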