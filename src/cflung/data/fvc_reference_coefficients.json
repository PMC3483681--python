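{
  "description": "Adult FVC reference-equation coefficients (litres) of the form FVC = b0 + b1*age + b2*age^2 + b3*height^2, with age in years and height in cm. Values are the NHANES III Caucasian adult coefficients published by Hankinson, Odencrantz & Fedan (1999). The male equation is nominally for ages >= 20; this fixture applies it from age 18, a <2-year extrapolation.",
  "units": {"fvc": "L", "age": "years", "height": "cm"},
  "support": {"age_min": 18.0, "age_max": 80.0, "height_min": 130.0, "height_max": 210.0},
  "male": {"b0": -0.1933, "b_age": 0.00064, "b_age2": -0.000269, "b_height2": 0.00018642},
  "female": {"b0": -0.3560, "b_age": 0.01870, "b_age2": -0.000382, "b_height2": 0.00014815}
}
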