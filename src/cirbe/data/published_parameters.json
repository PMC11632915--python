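{
  "resource_version": "1.0",
  "description": "Published free-parameter values of the empirical carbon-ion RBE model, with per-parameter standard uncertainties and the full parameter covariance. Dose units Gy; LET_d units keV/um.",
  "parameters": {
    "f1": 2.095070e-2,
    "m1": 5.955453e-1,
    "q1": 2.133918e-5,
    "f2": 2.230798e-2
  },
  "units": {
    "f1": "(keV/um)^-1",
    "m1": "Gy",
    "q1": "(keV/um)^-2",
    "f2": "(keV/um)^-1"
  },
  "uncertainties": {
    "f1": 8.575542e-3,
    "m1": 4.089380e-1,
    "q1": 8.756112e-6,
    "f2": 3.479508e-3
  },
  "covariances": {
    "f1,m1": 2.945233e-3,
    "f1,q1": 4.704403e-9,
    "f1,f2": 1.172688e-6,
    "q1,m1": -8.767703e-7,
    "m1,f2": -6.539078e-6,
    "q1,f2": 1.257442e-9
  }
}
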