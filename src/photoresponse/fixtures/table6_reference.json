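{
  "schema": "photoresponse/1",
  "description": "Printed rapid-light-curve fit results (reference values at table precision). The per-repeat alpha/etr_max/i_k triples satisfy alpha = etr_max/i_k but are not consistent with alpha = 1/c for the printed c values; they are carried as reference only.",
  "repeats": [
    {"repeat": 1, "fvfm_etr_half": 0.241, "alpha": 0.043, "etr_max": 21.4, "i_k": 493.1, "fvfm": 0.5727, "a": -6.637e-06, "b": 0.06827, "c": 11.5297, "r_squared": 0.993},
    {"repeat": 2, "fvfm_etr_half": 0.236, "alpha": 0.046, "etr_max": 19.4, "i_k": 425.6, "fvfm": 0.5616, "a": -9.711e-07, "b": 0.04571, "c": 21.197, "r_squared": 0.987},
    {"repeat": 3, "fvfm_etr_half": 0.226, "alpha": 0.06, "etr_max": 25.8, "i_k": 427.2, "fvfm": 0.5383, "a": -3.762e-06, "b": 0.05887, "c": 10.0040, "r_squared": 0.952}
  ],
  "average": {"fvfm_etr_half": 0.2343, "alpha": 0.0497, "etr_max": 22.2, "i_k": 448.63, "fvfm": 0.5575, "a": -3.79e-06, "b": 0.0576, "c": 14.24, "r_squared": 0.977}
}
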