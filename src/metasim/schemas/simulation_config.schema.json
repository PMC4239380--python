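{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "SimulationConfig",
  "type": "object",
  "required": ["primary", "colonization", "duration"],
  "properties": {
    "primary": {
      "type": "object",
      "required": ["a"],
      "properties": {
        "a": {"type": "number", "exclusiveMinimum": 0, "description": "primary growth-rate constant, day^-1"},
        "b": {"type": "number", "exclusiveMinimum": 1, "default": 4.5e9, "description": "saturation size, cells"},
        "x0": {"type": "number", "minimum": 1, "default": 1e4, "description": "surviving inoculum, cells"}
      }
    },
    "colonization": {
      "type": "object",
      "required": ["m"],
      "properties": {
        "m": {"type": "number", "minimum": 0, "description": "colonization constant, (cell*day)^-1"},
        "alpha": {"type": "number", "exclusiveMinimum": 0, "maximum": 1, "default": 0.663, "description": "fractal dimension of tumour vasculature"}
      }
    },
    "duration": {"type": "number", "exclusiveMinimum": 0, "description": "simulated horizon, days"},
    "kill_probability": {"type": "number", "minimum": 0, "maximum": 1, "default": 0},
    "metastasis_growth_factor": {"type": "number", "exclusiveMinimum": 0, "default": 1, "description": "metastasis growth rate as a fraction of the primary constant (1/3, 1/2 or 1)"},
    "dormancy": {
      "type": "object",
      "properties": {
        "kind": {"enum": ["none", "dormancy", "late_dormancy"]},
        "mean_duration": {"type": "number", "minimum": 0},
        "sd_duration": {"type": "number", "minimum": 0},
        "size_mean": {"type": "number"},
        "size_sd": {"type": "number", "minimum": 0},
        "size_min": {"type": "number", "minimum": 2},
        "size_max": {"type": "number"}
      }
    },
    "snapshot_interval": {"type": "number", "exclusiveMinimum": 0, "default": 1},
    "replicates": {"type": "integer", "minimum": 1, "default": 100},
    "seed": {"type": "integer", "default": 0}
  }
}
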