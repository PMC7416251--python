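{
  "$defs": {
    "Phase1Entry": {
      "additionalProperties": false,
      "properties": {
        "params": {
          "additionalProperties": true,
          "title": "Params",
          "type": "object"
        },
        "rpt": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Rpt"
        },
        "silhouette": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Silhouette"
        }
      },
      "required": [
        "silhouette",
        "rpt",
        "params"
      ],
      "title": "Phase1Entry",
      "type": "object"
    },
    "Phase2Row": {
      "additionalProperties": false,
      "properties": {
        "AC": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ac"
        },
        "ARI": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ari"
        },
        "Dunn": {
          "title": "Dunn",
          "type": "number"
        },
        "F": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "F"
        },
        "HI": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Hi"
        },
        "I": {
          "title": "I",
          "type": "integer"
        },
        "RI": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ri"
        },
        "RPT": {
          "title": "Rpt",
          "type": "number"
        },
        "SSE": {
          "title": "Sse",
          "type": "number"
        },
        "Si": {
          "title": "Si",
          "type": "number"
        },
        "VI": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Vi"
        }
      },
      "required": [
        "I",
        "SSE",
        "Si",
        "RPT",
        "Dunn"
      ],
      "title": "Phase2Row",
      "type": "object"
    },
    "Provenance": {
      "additionalProperties": false,
      "properties": {
        "config_hash": {
          "title": "Config Hash",
          "type": "string"
        },
        "ga": {
          "additionalProperties": true,
          "title": "Ga",
          "type": "object"
        },
        "gap_B": {
          "title": "Gap B",
          "type": "integer"
        },
        "restarts": {
          "title": "Restarts",
          "type": "integer"
        },
        "rpt_B": {
          "title": "Rpt B",
          "type": "integer"
        },
        "seed": {
          "title": "Seed",
          "type": "integer"
        },
        "version": {
          "title": "Version",
          "type": "string"
        }
      },
      "required": [
        "seed",
        "restarts",
        "rpt_B",
        "gap_B",
        "ga",
        "config_hash",
        "version"
      ],
      "title": "Provenance",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "One dataset's results in the shape of the published tables.",
  "properties": {
    "convergence": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Convergence",
      "type": "object"
    },
    "dataset": {
      "title": "Dataset",
      "type": "string"
    },
    "k_used": {
      "title": "K Used",
      "type": "integer"
    },
    "k_votes": {
      "anyOf": [
        {
          "additionalProperties": {
            "type": "integer"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "K Votes"
    },
    "phase1": {
      "additionalProperties": {
        "$ref": "#/$defs/Phase1Entry"
      },
      "title": "Phase1",
      "type": "object"
    },
    "phase1_best": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Phase1 Best",
      "type": "object"
    },
    "phase2": {
      "additionalProperties": {
        "$ref": "#/$defs/Phase2Row"
      },
      "title": "Phase2",
      "type": "object"
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    }
  },
  "required": [
    "dataset",
    "k_used",
    "phase1",
    "phase1_best",
    "phase2",
    "convergence",
    "provenance"
  ],
  "title": "StudyReport",
  "type": "object"
}
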