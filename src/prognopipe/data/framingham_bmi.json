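{
  "description": "Office-based (non-laboratory, BMI) general cardiovascular risk equation: per-gender Cox coefficients on log-transformed predictors, baseline survival at 10 years, and the population mean linear predictor. Source: the published Framingham general CVD risk functions (D'Agostino et al., Circulation 2008; framinghamheartstudy.org risk calculator).",
  "version": "2008-bmi",
  "male": {
    "ln_age": 3.11296,
    "ln_bmi": 0.79277,
    "ln_sbp_untreated": 1.85508,
    "ln_sbp_treated": 1.92672,
    "smoking": 0.70953,
    "diabetes": 0.53160,
    "baseline_survival_10y": 0.88431,
    "mean_linear_predictor": 23.9802
  },
  "female": {
    "ln_age": 2.72107,
    "ln_bmi": 0.51125,
    "ln_sbp_untreated": 2.81291,
    "ln_sbp_treated": 2.88267,
    "smoking": 0.61868,
    "diabetes": 0.77763,
    "baseline_survival_10y": 0.94833,
    "mean_linear_predictor": 26.0145
  }
}
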