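{
  "seed": 1,
  "out_dir": "scratch/demo_run",
  "bg_mode": "per-spot",
  "p_gate": "lt",
  "up": 1.5,
  "down": 0.67,
  "contrasts": [["SAD", "SAD-C"], ["M16", "MC"], ["M48", "MC"]],
  "compare": {"a": [["SAD", "SAD-C"]], "b": [["M16", "MC"], ["M48", "MC"]]},
  "heatmap": {"contrasts": [["M16", "MC"], ["M48", "MC"]], "rows": "groups"},
  "simulate": {
    "groups": [
      {"group_id": "SAD", "role": "model",
       "fold": {"WFA": 0.4, "PTL-I": 0.2, "PTL-II": 0.4, "PHA-E + L": 0.3,
                "SNA": 0.4, "PSA": 2.5}},
      {"group_id": "SAD-C", "role": "control"},
      {"group_id": "M16", "role": "model",
       "fold": {"WFA": 2.5, "PTL-I": 2.6, "PTL-II": 1.9, "PHA-E + L": 1.7,
                "SNA": 1.6, "ConA": 0.4}},
      {"group_id": "M48", "role": "model",
       "fold": {"WFA": 2.2, "PTL-I": 1.8, "PTL-II": 1.9, "PHA-E + L": 2.0,
                "SNA": 1.7, "ConA": 0.4}},
      {"group_id": "MC", "role": "control"}
    ],
    "baseline_mu": 7.0,
    "spot_cv": 0.05,
    "block_sd": 0.05,
    "slide_sd": 0.05,
    "bg_level": 100.0,
    "bg_sd": 5.0
  }
}
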