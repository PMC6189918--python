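{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "depfield run configuration",
  "description": "YAML configuration accepted by the depfield CLI. Quantities may be plain numbers (SI units) or strings with a unit suffix, e.g. '150 um', '3 mV', '1e-3 S/m'. Lengths are metres, voltages volts, conductivities S/m, angular frequencies rad/s (Hz suffixes are converted to rad/s).",
  "type": "object",
  "required": ["geometry"],
  "properties": {
    "geometry": {
      "type": "object",
      "required": ["width", "height", "n_top", "n_bottom"],
      "properties": {
        "width": {"description": "Channel width L (length quantity)"},
        "height": {"description": "Channel height h (length quantity)"},
        "n_top": {"type": "integer", "minimum": 2, "description": "Electrodes on the top wall (N+)"},
        "n_bottom": {"type": "integer", "minimum": 2, "description": "Electrodes on the bottom wall (N-)"}
      }
    },
    "medium": {
      "type": "object",
      "properties": {
        "rel_permittivity": {"type": "number", "default": 78, "description": "Relative medium permittivity em"},
        "conductivity": {"description": "Medium conductivity (S/m quantity)", "default": 0},
        "wall_rel_permittivity": {"type": "number", "default": 4, "description": "Relative wall permittivity ew"}
      }
    },
    "particle": {
      "type": "object",
      "required": ["radius"],
      "properties": {
        "radius": {"description": "Particle radius r (length quantity)"},
        "rel_permittivity": {"type": "number", "default": 2.5},
        "conductivity": {"description": "Particle conductivity (S/m quantity)", "default": 0}
      }
    },
    "drive": {
      "type": "object",
      "description": "Either an angular frequency or a direct Re(beta) override.",
      "properties": {
        "frequency": {"description": "Drive angular frequency (rad/s quantity; Hz suffixes converted)"},
        "cm_real": {"type": "number", "minimum": -0.5, "maximum": 1.0, "description": "Clausius-Mossotti real part override"}
      }
    },
    "voltages": {
      "type": "object",
      "required": ["top", "bottom"],
      "properties": {
        "top": {"type": "array", "items": {"type": "number"}, "description": "Per-electrode voltages of the top array (V), left to right"},
        "bottom": {"type": "array", "items": {"type": "number"}, "description": "Per-electrode voltages of the bottom array (V), left to right"}
      }
    },
    "model": {
      "type": "object",
      "properties": {
        "p_harmonics": {"type": "integer", "minimum": 1, "description": "Truncation order P (default 2 max(N+, N-))"}
      }
    },
    "solver": {
      "type": "object",
      "properties": {
        "spacing": {"description": "Reference-solver grid spacing (length quantity, <= 1 um, must divide L and h)", "default": "0.5 um"}
      }
    },
    "roi": {
      "type": "object",
      "properties": {
        "y": {"type": "array", "items": {"type": "number"}, "description": "Fractional y-range of the region of interest, inside (0, 1)"},
        "z": {"type": "array", "items": {"type": "number"}, "description": "Fractional z-range (dual frame), inside (-0.5, 0.5)"}
      }
    },
    "seed": {"type": "integer", "default": 0, "description": "Seed for random voltage draws"}
  }
}
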