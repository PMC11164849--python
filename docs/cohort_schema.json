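{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "CPX cohort record",
  "description": "JSON mirror of the long-format cohort CSV (one CSV row per stage with participant metadata repeated; missing values are empty CSV fields / JSON nulls). Loads are watts on the bicycle and km/h on the treadmill.",
  "type": "object",
  "required": ["participant_id", "test_date", "age", "sex", "ergometry", "height_cm", "weight_kg", "vo2max", "stages"],
  "properties": {
    "participant_id": {"type": "string", "minLength": 1},
    "test_date": {"type": "string", "format": "date"},
    "age": {"type": "number", "exclusiveMinimum": 0},
    "sex": {"enum": ["male", "female"]},
    "ergometry": {"type": "string", "description": "bicycle/treadmill analysed; other values excluded under criterion E"},
    "height_cm": {"type": "number", "exclusiveMinimum": 0},
    "weight_kg": {"type": "number", "exclusiveMinimum": 0},
    "vo2max": {"type": "number", "description": "ml/kg/min"},
    "resting_bla": {"type": ["number", "null"], "description": "mmol/l, pre-test sample"},
    "stages": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["stage_index", "load"],
        "properties": {
          "stage_index": {"type": "integer", "minimum": 1, "description": "consecutive from 1"},
          "load": {"type": "number", "description": "strictly increasing across stages"},
          "duration_min": {"type": "number", "const": 3.0},
          "bla": {"type": ["number", "null"], "exclusiveMinimum": 0, "description": "mmol/l, end of stage"},
          "rpe": {"type": ["integer", "null"], "minimum": 6, "maximum": 20}
        }
      }
    }
  }
}
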