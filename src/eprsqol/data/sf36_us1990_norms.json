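{
 "comment": "US general-population (1990) SF-36 domain means/SDs and PCS/MCS factor-score coefficients, as published with the original component-summary scoring.",
 "means": {"pf": 84.15215, "rp": 81.19907, "bp": 75.49196, "gh": 72.21316,
           "vt": 61.05453, "sf": 83.59753, "re": 81.29467, "mh": 74.84212},
 "sds":   {"pf": 22.89490, "rp": 33.79729, "bp": 23.55879, "gh": 20.16964,
           "vt": 20.86942, "sf": 22.37642, "re": 33.02717, "mh": 18.01189},
 "coef_pcs": {"pf": 0.42402, "rp": 0.35119, "bp": 0.31754, "gh": 0.24954,
              "vt": 0.02877, "sf": -0.00753, "re": -0.19206, "mh": -0.22069},
 "coef_mcs": {"pf": -0.22999, "rp": -0.12329, "bp": -0.09731, "gh": -0.01571,
              "vt": 0.23534, "sf": 0.26876, "re": 0.43407, "mh": 0.48581}
}
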