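{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "focalspot measurement report",
  "type": "object",
  "required": ["kind", "offset_mm", "geometry_mm", "software", "generated", "report_version"],
  "properties": {
    "kind": {"enum": ["epid", "ic"]},
    "report_version": {"type": "integer"},
    "generated": {"type": "string", "format": "date-time"},
    "software": {
      "type": "object",
      "required": ["name", "version"],
      "properties": {"name": {"type": "string"}, "version": {"type": "string"}}
    },
    "offset_mm": {
      "type": "object",
      "required": ["crossplane", "inplane"],
      "properties": {
        "crossplane": {"type": ["number", "null"]},
        "inplane": {"type": ["number", "null"]}
      }
    },
    "geometry_mm": {
      "type": "object",
      "required": ["d_epi", "d_jaw_x", "d_jaw_y", "d_mlc", "d_ic", "sad"],
      "additionalProperties": {"type": "number"}
    },
    "field_centers_mm": {
      "type": "object",
      "description": "EPID reports only: per-image centres keyed jaw_90/jaw_270/mlc_90/mlc_270",
      "additionalProperties": {
        "type": "object",
        "required": ["u", "v"],
        "properties": {
          "u": {"type": "number"},
          "v": {"type": "number"},
          "source": {"type": "string"}
        }
      }
    },
    "jaw_centroid_mm": {"$ref": "#/$defs/uv"},
    "mlc_centroid_mm": {"$ref": "#/$defs/uv"},
    "separation_mm": {
      "type": "object",
      "properties": {"u": {"type": "number"}, "v": {"type": "number"}}
    },
    "factors": {
      "type": "object",
      "properties": {"u": {"type": "number"}, "v": {"type": "number"}}
    },
    "jaw_mapping": {"type": "object"},
    "axis_pairing": {"enum": ["x-inplane", "x-crossplane"]},
    "effective_pitch_mm": {"type": "number"},
    "params": {"type": "object"},
    "sensitivities": {
      "type": "object",
      "description": "ion-chamber reports only: per-jaw OLS sensitivity fits",
      "additionalProperties": {
        "type": "object",
        "required": ["slope_nc_per_mm", "r_squared", "n"],
        "properties": {
          "slope_nc_per_mm": {"type": "number"},
          "intercept_nc": {"type": "number"},
          "r_squared": {"type": "number"},
          "residual_max_nc": {"type": "number"},
          "n": {"type": "integer"}
        }
      }
    },
    "offsets_by_jaw_mm": {"type": "object"}
  },
  "$defs": {
    "uv": {
      "type": "object",
      "required": ["u", "v"],
      "properties": {"u": {"type": "number"}, "v": {"type": "number"}}
    }
  }
}
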