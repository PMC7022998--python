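{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "adaptgeom ensemble report",
  "type": "object",
  "required": [
    "athlete_id",
    "combination",
    "mean_gapi",
    "mean_gof",
    "gapi_sd",
    "degenerate_members",
    "misclassified_weeks",
    "config",
    "members"
  ],
  "properties": {
    "athlete_id": {"type": "string"},
    "combination": {"type": "integer"},
    "mean_gapi": {"type": ["number", "null"]},
    "mean_gof": {"type": "number"},
    "gapi_sd": {"type": "number"},
    "degenerate_members": {"type": "integer"},
    "misclassified_weeks": {"type": "array", "items": {"type": "integer"}},
    "config": {
      "type": "object",
      "required": [
        "seed",
        "noise_level",
        "replicates",
        "multiplicative",
        "layer_width",
        "buffer_radius",
        "grid_resolution"
      ],
      "properties": {
        "seed": {"type": "integer"},
        "noise_level": {"type": "number"},
        "replicates": {"type": "integer"},
        "multiplicative": {"type": "boolean"},
        "layer_width": {"type": "number"},
        "buffer_radius": {"type": "number"},
        "grid_resolution": {"type": "integer"}
      }
    },
    "members": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "area_adapt",
          "area_malad",
          "area_neutral",
          "gapi",
          "gapi_infinite",
          "goodness_of_fit",
          "per_point"
        ],
        "properties": {
          "area_adapt": {"type": "number"},
          "area_malad": {"type": "number"},
          "area_neutral": {"type": "number"},
          "gapi": {"type": ["number", "null"]},
          "gapi_infinite": {"type": "boolean"},
          "goodness_of_fit": {"type": "integer"},
          "mce": {"type": "number"},
          "per_point": {"type": "object"}
        }
      }
    }
  }
}
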