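{
  "$defs": {
    "StageReportModel": {
      "additionalProperties": false,
      "properties": {
        "n_in": {
          "title": "N In",
          "type": "integer"
        },
        "n_out": {
          "title": "N Out",
          "type": "integer"
        },
        "removed_ids": {
          "items": {
            "type": "string"
          },
          "title": "Removed Ids",
          "type": "array"
        },
        "stage_name": {
          "title": "Stage Name",
          "type": "string"
        }
      },
      "required": [
        "stage_name",
        "n_in",
        "n_out",
        "removed_ids"
      ],
      "title": "StageReportModel",
      "type": "object"
    },
    "TopCompoundModel": {
      "additionalProperties": false,
      "properties": {
        "compound_id": {
          "title": "Compound Id",
          "type": "string"
        },
        "max_possible": {
          "title": "Max Possible",
          "type": "number"
        },
        "normalized_score": {
          "title": "Normalized Score",
          "type": "number"
        },
        "rank": {
          "title": "Rank",
          "type": "integer"
        },
        "raw_score": {
          "title": "Raw Score",
          "type": "number"
        }
      },
      "required": [
        "compound_id",
        "raw_score",
        "max_possible",
        "normalized_score",
        "rank"
      ],
      "title": "TopCompoundModel",
      "type": "object"
    },
    "VotePairModel": {
      "additionalProperties": false,
      "properties": {
        "compound_id": {
          "title": "Compound Id",
          "type": "string"
        },
        "target_id": {
          "title": "Target Id",
          "type": "string"
        },
        "votes": {
          "title": "Votes",
          "type": "integer"
        }
      },
      "required": [
        "compound_id",
        "target_id",
        "votes"
      ],
      "title": "VotePairModel",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Validated, fully regenerable run report.",
  "properties": {
    "artifacts": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Artifacts",
      "type": "object"
    },
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "n_scored": {
      "title": "N Scored",
      "type": "integer"
    },
    "package_version": {
      "title": "Package Version",
      "type": "string"
    },
    "ruleset": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Ruleset",
      "type": "array"
    },
    "schema_version": {
      "default": 1,
      "title": "Schema Version",
      "type": "integer"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "stages": {
      "items": {
        "$ref": "#/$defs/StageReportModel"
      },
      "title": "Stages",
      "type": "array"
    },
    "top_compounds": {
      "items": {
        "$ref": "#/$defs/TopCompoundModel"
      },
      "title": "Top Compounds",
      "type": "array"
    },
    "votes": {
      "anyOf": [
        {
          "items": {
            "$ref": "#/$defs/VotePairModel"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Votes"
    }
  },
  "required": [
    "package_version",
    "seed",
    "config",
    "stages",
    "ruleset",
    "n_scored",
    "top_compounds",
    "artifacts"
  ],
  "title": "ScreeningReport",
  "type": "object"
}
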