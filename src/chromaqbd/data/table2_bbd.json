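{
  "description": "Box-Behnken optimization study of the three critical method parameters (16 runs incl. 4 centre points); responses are peak begin/end retention times in minutes.",
  "factors": [
    {"name": "ACN at gradient start", "symbol": "A", "low": 37.0, "high": 41.0, "units": "%", "grid_levels": 21},
    {"name": "chaotropic salt concentration", "symbol": "B", "low": 30.0, "high": 60.0, "units": "mM", "grid_levels": 21},
    {"name": "gradient start time", "symbol": "C", "low": 7.0, "high": 11.0, "units": "min", "grid_levels": 11}
  ],
  "responses": ["t_e_bup", "t_b_imp2", "t_e_imp2", "t_b_imp3"]
}
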