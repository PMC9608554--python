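{
  "description": "2^(6-2) fractional factorial screening study of the gradient chaotropic HPLC method (19 runs incl. 3 centre points); responses are peak begin/end retention times in minutes.",
  "factors": [
    {"name": "pH of aqueous mobile phase", "symbol": "A", "low": 2.4, "high": 4.0, "units": "pH", "grid_levels": 2},
    {"name": "ACN at gradient start", "symbol": "B", "low": 37.0, "high": 43.0, "units": "%", "grid_levels": 2},
    {"name": "chaotropic salt concentration", "symbol": "C", "low": 20.0, "high": 80.0, "units": "mM", "grid_levels": 2},
    {"name": "column temperature", "symbol": "D", "low": 30.0, "high": 40.0, "units": "degC", "grid_levels": 2},
    {"name": "gradient start time", "symbol": "E", "low": 5.0, "high": 8.0, "units": "min", "grid_levels": 2},
    {"name": "gradient end time", "symbol": "F", "low": 9.0, "high": 13.0, "units": "min", "grid_levels": 2}
  ],
  "responses": ["t_e_bup", "t_b_imp2", "t_e_imp2", "t_b_imp3", "t_R_imp5"]
}
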