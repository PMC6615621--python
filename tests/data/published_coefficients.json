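{
  "d1": {
    "intercept": -9.59,
    "exponents": {"hr": 2.39, "age": 0.274, "sex": -0.204, "fvc": 0.520}
  },
  "d2": {
    "intercept": -8.57,
    "exponents": {"hr": 1.72, "fb": 0.611, "age": 0.298, "sex": -0.206, "fvc": 0.614}
  },
  "legacy": {
    "zuurbier": {"family": "exp_linear_hr", "coefficients": {"1": [1.03, 0.021], "2": [0.57, 0.023]}},
    "ramos": {"family": "exp_linear_hr", "coefficients": {"1": [1.17, 0.02], "2": [0.99, 0.02]}},
    "cozza": {"family": "exp_linear_hr", "coefficients": {"all": [0.58, 0.025]}},
    "do_vale": {"family": "power_hr", "coefficients": {"all": [0.00071, 2.17]}},
    "mcardle": {"family": "fb_log", "coefficients": {"all": [1.8028, -3.8881]}},
    "greenwald2014": {"family": "linear_hr_fb", "coefficients": {"all": [-4.247, 0.0595, 0.226]}}
  }
}
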