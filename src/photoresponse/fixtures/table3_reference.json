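{
  "schema": "photoresponse/1",
  "description": "Printed fitted parameters and derived cardinal points of the light and CO2 response curves (reference values at table precision).",
  "light": [
    {"repeat": 1, "e": 0.0536, "m": 0.000230, "n": 0.01465, "cp": 14.017, "sp": 534.52, "dark_respiration": 0.751, "rate_at_sp": 2.771, "r_squared": 0.979},
    {"repeat": 2, "e": 0.01496, "m": 0.000304, "n": 0.002298, "cp": 17.67, "sp": 863.54, "dark_respiration": 0.264, "rate_at_sp": 3.127, "r_squared": 0.987},
    {"repeat": 3, "e": 0.0284, "m": 0.000389, "n": 0.00647, "cp": 15.314, "sp": 525.84, "dark_respiration": 0.435, "rate_at_sp": 2.620, "r_squared": 0.993}
  ],
  "light_average": {"e": 0.03232, "m": 0.000308, "n": 0.007806, "cp": 15.667, "sp": 641.30, "dark_respiration": 0.483, "rate_at_sp": 2.839, "r_squared": 0.986},
  "co2": [
    {"repeat": 1, "e": 0.01113, "m": 0.000309, "n": 0.000001, "cp": 35.56, "sp": 1634.6, "dark_respiration": 0.396, "rate_at_sp": 8.794, "r_squared": 0.973},
    {"repeat": 2, "e": 0.01011, "m": 0.0002707, "n": 0.000001, "cp": 51.16, "sp": 1871.0, "dark_respiration": 0.517, "rate_at_sp": 9.063, "r_squared": 0.982},
    {"repeat": 3, "e": 0.01049, "m": 0.000283, "n": 0.000001, "cp": 58.72, "sp": 1794.6, "dark_respiration": 0.616, "rate_at_sp": 8.945, "r_squared": 0.988}
  ],
  "co2_average": {"e": 0.010577, "m": 0.000288, "n": 0.000001, "cp": 48.48, "sp": 1766.7, "dark_respiration": 0.5097, "rate_at_sp": 8.934, "r_squared": 0.981}
}
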