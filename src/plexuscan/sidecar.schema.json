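{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "plexuscan volume sidecar (meta.json)",
  "type": "object",
  "required": ["extent_x_mm", "extent_y_mm", "n_ascans", "n_bscans",
               "n_depth", "axial_px_um", "centre_offset_mm"],
  "properties": {
    "extent_x_mm": {"type": "number", "exclusiveMinimum": 0},
    "extent_y_mm": {"type": "number", "exclusiveMinimum": 0},
    "n_ascans": {"type": "integer", "minimum": 1},
    "n_bscans": {"type": "integer", "minimum": 1},
    "n_depth": {"type": "integer", "minimum": 1},
    "axial_px_um": {"type": "number", "exclusiveMinimum": 0},
    "centre_offset_mm": {
      "type": "array", "items": {"type": "number"},
      "minItems": 2, "maxItems": 2
    },
    "signal_strength": {"type": "integer", "minimum": 0, "maximum": 10},
    "n_corrected_bscans": {"type": "integer", "minimum": 0},
    "seed": {"type": ["integer", "null"]}
  }
}
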