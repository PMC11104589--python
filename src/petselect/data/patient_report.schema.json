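{
  "$defs": {
    "StageReport": {
      "description": "DSI profile and PCC of one executed evaluation stage.",
      "properties": {
        "dsi": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Dsi",
          "type": "object"
        },
        "margin": {
          "title": "Margin",
          "type": "number"
        },
        "pcc": {
          "title": "Pcc",
          "type": "number"
        },
        "stage": {
          "enum": [
            "baseline",
            "hyp_pos",
            "hyp_neg",
            "actual"
          ],
          "title": "Stage",
          "type": "string"
        },
        "title": {
          "title": "Title",
          "type": "string"
        },
        "top_label": {
          "title": "Top Label",
          "type": "string"
        }
      },
      "required": [
        "stage",
        "title",
        "dsi",
        "top_label",
        "margin",
        "pcc"
      ],
      "title": "StageReport",
      "type": "object"
    }
  },
  "description": "Schema-stable per-patient decision report.",
  "properties": {
    "advice": {
      "title": "Advice",
      "type": "string"
    },
    "advice_trail": {
      "items": {
        "type": "string"
      },
      "title": "Advice Trail",
      "type": "array"
    },
    "diagnosed": {
      "title": "Diagnosed",
      "type": "boolean"
    },
    "final_label": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Final Label"
    },
    "group": {
      "maximum": 4,
      "minimum": 1,
      "title": "Group",
      "type": "integer"
    },
    "patient_id": {
      "title": "Patient Id",
      "type": "string"
    },
    "pet_performed": {
      "title": "Pet Performed",
      "type": "boolean"
    },
    "stages": {
      "items": {
        "$ref": "#/$defs/StageReport"
      },
      "title": "Stages",
      "type": "array"
    }
  },
  "required": [
    "patient_id",
    "group",
    "pet_performed",
    "diagnosed",
    "advice",
    "advice_trail",
    "stages"
  ],
  "title": "PatientReport",
  "type": "object"
}
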