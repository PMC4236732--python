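{
  "version": 1,
  "comment": "Second-round response-surface models for C. reinhardtii bioenergetic responses; coefficients at full printed precision. factor_means are the fit-sample means used as profile defaults (CR was fitted on 40 runs, hence its own acetate/ammonium means).",
  "models": {
    "CR": {
      "response": "CR",
      "unit": "nmolO2.min-1.mg_proteins-1",
      "intercept": 6.67,
      "linear": {"acetate": 9.01, "light": 0.0259, "ammonium": -0.428},
      "quadratic": [],
      "interaction": [
        {"factor_a": "acetate", "factor_b": "ammonium", "coef": -0.566,
         "center_a": 0.463, "center_b": 7.69}
      ],
      "factor_means": {"acetate": 0.463, "light": 107, "ammonium": 7.69}
    },
    "MA_CYT": {
      "response": "MA_CYT",
      "unit": "nmolO2.min-1.mg_proteins-1",
      "intercept": 5.81,
      "linear": {"acetate": 7.58, "light": 0.0264, "ammonium": -0.283},
      "quadratic": [],
      "interaction": [],
      "factor_means": {"acetate": 0.488, "light": 107, "ammonium": 7.32}
    },
    "MA_ALT": {
      "response": "MA_ALT",
      "unit": "nmolO2.min-1.mg_proteins-1",
      "intercept": 11.1,
      "linear": {"acetate": 3.64, "light": 0.0210, "ammonium": -0.318},
      "quadratic": [
        {"factor": "acetate", "coef": -13.5, "center": 0.488}
      ],
      "interaction": [
        {"factor_a": "acetate", "factor_b": "ammonium", "coef": -0.383,
         "center_a": 0.488, "center_b": 7.32}
      ],
      "factor_means": {"acetate": 0.488, "light": 107, "ammonium": 7.32}
    },
    "PHIPSII800": {
      "response": "PHIPSII800",
      "unit": "dimensionless",
      "intercept": 0.308,
      "linear": {"light": 0.00103},
      "quadratic": [],
      "interaction": [],
      "factor_means": {"light": 107}
    },
    "NPQ800": {
      "response": "NPQ800",
      "unit": "dimensionless",
      "intercept": 0.334,
      "linear": {"acetate": -0.0877, "light": -0.000146, "nitrate": -0.00146},
      "quadratic": [
        {"factor": "nitrate", "coef": -0.00109, "center": 9.76}
      ],
      "interaction": [
        {"factor_a": "acetate", "factor_b": "light", "coef": -0.000918,
         "center_a": 0.488, "center_b": 107}
      ],
      "factor_means": {"acetate": 0.488, "light": 107, "nitrate": 9.76}
    },
    "P800": {
      "response": "P800",
      "unit": "nmolO2.min-1.mg_proteins-1",
      "intercept": 42.3,
      "linear": {"acetate": -3.18, "light": 0.185, "nitrate": 0.879},
      "quadratic": [
        {"factor": "acetate", "coef": 183, "center": 0.488},
        {"factor": "nitrate", "coef": -0.608, "center": 9.76}
      ],
      "interaction": [],
      "factor_means": {"acetate": 0.488, "light": 107, "nitrate": 9.76}
    }
  }
}
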