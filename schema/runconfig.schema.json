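{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "avtbw run configuration",
  "description": "Schema for YAML run configs consumed by RunConfig.from_yaml. A config may name a preset (exp1 | exp2 | exp3) and override any default.",
  "type": "object",
  "properties": {
    "preset": {"enum": ["exp1", "exp2", "exp3", "custom"]},
    "sample_rate_hz": {"type": "number", "exclusiveMinimum": 0},
    "audio_sample_rate_hz": {"type": "integer", "exclusiveMinimum": 0},
    "carrier_hz": {"type": "number", "exclusiveMinimum": 0},
    "soa_grid_ms": {
      "type": "array",
      "items": {"type": "number"},
      "minItems": 1,
      "uniqueItems": true
    },
    "max_soa_ms": {"type": "number", "exclusiveMinimum": 0},
    "n_reps": {"type": "integer", "minimum": 1},
    "fft_band_hz": {
      "type": "array",
      "items": {"type": "number", "exclusiveMinimum": 0},
      "minItems": 2,
      "maxItems": 2
    },
    "speech_target_hz": {"type": "number", "exclusiveMinimum": 0},
    "speech_tol_hz": {"type": "number", "minimum": 0},
    "speech_jitter_cv": {"type": "number", "minimum": 0, "maximum": 0.5},
    "speech_amp_cv": {"type": "number", "minimum": 0, "maximum": 0.5},
    "n_speech_tokens": {"type": "integer", "minimum": 1},
    "gauss_r2_threshold": {"type": "number"},
    "logistic_r2_threshold": {"type": "number"},
    "priors": {
      "type": "object",
      "properties": {
        "a_range": {"$ref": "#/$defs/range01"},
        "b_mean": {"type": "number"},
        "b_sd": {"type": "number", "minimum": 0},
        "c_range": {"$ref": "#/$defs/positiveRange"},
        "unsure_range": {"$ref": "#/$defs/range01"},
        "confident_range": {"$ref": "#/$defs/range01"}
      },
      "additionalProperties": false
    },
    "conditions": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["label", "mode", "freq_hz"],
        "properties": {
          "label": {"type": "string"},
          "mode": {"enum": ["rhythmic", "speech-like"]},
          "freq_hz": {"type": "number", "exclusiveMinimum": 0},
          "stream_mode": {"enum": ["fixed_duration", "fixed_pulses"]},
          "stream_value": {"type": "number", "exclusiveMinimum": 0},
          "envelope_label": {"type": ["string", "null"]}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false,
  "$defs": {
    "range01": {
      "type": "array",
      "items": {"type": "number", "minimum": 0, "maximum": 1},
      "minItems": 2,
      "maxItems": 2
    },
    "positiveRange": {
      "type": "array",
      "items": {"type": "number", "exclusiveMinimum": 0},
      "minItems": 2,
      "maxItems": 2
    }
  }
}
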