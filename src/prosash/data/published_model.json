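{
  "version": "prosash-1.0",
  "description": "Published PROSASH model: flexible parametric (spline on log cumulative hazard) survival model for sorafenib-treated advanced HCC, fitted on the brivanib-trial sorafenib arm (n=500 complete cases).",
  "age_center": 60.0,
  "coefficients": {
    "vascular_invasion": 0.327,
    "age_centered": -0.0231,
    "age_x_vi": 0.0303,
    "ecog1": 0.455,
    "ln_afp": 0.0831,
    "albumin": -0.0553,
    "ln_creatinine": 0.709,
    "ln_ast": 0.349,
    "ehs": 0.298,
    "hbv": 0.526,
    "other_aetiology": 0.507
  },
  "spline": {
    "boundary_knots": [-1.017, 3.443],
    "internal_knots": [1.833],
    "gamma": [-8.167, 2.465, 0.113]
  },
  "risk_cutoffs": [2.898, 3.666, 4.559],
  "follow_up_horizon_months": 31.28,
  "units": {
    "time": "months",
    "age": "years",
    "afp": "ng/ml",
    "albumin": "g/l",
    "creatinine": "umol/L",
    "ast": "U/L"
  }
}
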