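{
  "$defs": {
    "Aggregates": {
      "additionalProperties": false,
      "properties": {
        "mean_acc": {
          "title": "Mean Acc",
          "type": "number"
        },
        "mean_sen": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Mean Sen"
        },
        "mean_spe": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Mean Spe"
        },
        "sd_acc": {
          "title": "Sd Acc",
          "type": "number"
        }
      },
      "required": [
        "mean_acc",
        "mean_sen",
        "mean_spe",
        "sd_acc"
      ],
      "title": "Aggregates",
      "type": "object"
    },
    "FoldRecord": {
      "additionalProperties": false,
      "properties": {
        "acc": {
          "title": "Acc",
          "type": "number"
        },
        "confusion": {
          "items": {
            "items": {
              "type": "integer"
            },
            "type": "array"
          },
          "title": "Confusion",
          "type": "array"
        },
        "fold": {
          "title": "Fold",
          "type": "integer"
        },
        "repeat": {
          "title": "Repeat",
          "type": "integer"
        },
        "sen": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Sen"
        },
        "spe": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Spe"
        }
      },
      "required": [
        "repeat",
        "fold",
        "confusion",
        "acc",
        "sen",
        "spe"
      ],
      "title": "FoldRecord",
      "type": "object"
    },
    "PermutationSection": {
      "additionalProperties": false,
      "properties": {
        "n_perm": {
          "title": "N Perm",
          "type": "integer"
        },
        "null_acc": {
          "items": {
            "type": "number"
          },
          "title": "Null Acc",
          "type": "array"
        },
        "observed_acc": {
          "title": "Observed Acc",
          "type": "number"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        }
      },
      "required": [
        "observed_acc",
        "n_perm",
        "null_acc",
        "p_value"
      ],
      "title": "PermutationSection",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Machine-readable pipeline report.",
  "properties": {
    "aggregates": {
      "$ref": "#/$defs/Aggregates"
    },
    "classes": {
      "items": {
        "type": "string"
      },
      "title": "Classes",
      "type": "array"
    },
    "classifier": {
      "title": "Classifier",
      "type": "string"
    },
    "n_features": {
      "title": "N Features",
      "type": "integer"
    },
    "n_subjects": {
      "title": "N Subjects",
      "type": "integer"
    },
    "pca": {
      "additionalProperties": true,
      "title": "Pca",
      "type": "object"
    },
    "per_fold": {
      "items": {
        "$ref": "#/$defs/FoldRecord"
      },
      "title": "Per Fold",
      "type": "array"
    },
    "permutation": {
      "anyOf": [
        {
          "$ref": "#/$defs/PermutationSection"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "repeats": {
      "title": "Repeats",
      "type": "integer"
    },
    "scheme": {
      "title": "Scheme",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "selected_k": {
      "items": {
        "type": "integer"
      },
      "title": "Selected K",
      "type": "array"
    }
  },
  "required": [
    "scheme",
    "classifier",
    "repeats",
    "seed",
    "n_subjects",
    "n_features",
    "classes",
    "pca",
    "selected_k",
    "per_fold",
    "aggregates"
  ],
  "title": "RunReport",
  "type": "object"
}
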