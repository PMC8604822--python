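{
 "schema_version": 1,
 "variant": "linked",
 "parameters": {
  "alpha_S1": -0.599,
  "alpha_S2_3": -1.11,
  "alpha_S3_4": -0.977,
  "alpha_S4_5": -0.806,
  "alpha_S5_6": -0.722,
  "alpha_S6_7": -0.78,
  "alpha_S7_8": -0.963,
  "alpha_S8_9": -1.21,
  "Smax_Sugar": 8.23,
  "SSugar50": 8.42,
  "SL_S_Fat": 0.00332,
  "omega2_S": 1.3,
  "omega2_Smax": 0.207,
  "alpha_C1": 1.155,
  "alpha_C2_3": -1.43,
  "alpha_C3_4": -1.05,
  "alpha_C4_5": -0.817,
  "alpha_C5_6": -0.834,
  "alpha_C6_7": -0.893,
  "alpha_C7_8": -1.12,
  "alpha_C8_9": -1.45,
  "SL_C_Fat": 0.183,
  "SL_C_Sugar": 0.0379,
  "omega2_C": 4.03,
  "alpha_P1": -1.38,
  "alpha_P2_3": -1.96,
  "alpha_P3_4": -1.5,
  "alpha_P4_5": -0.904,
  "alpha_P5_6": -0.407,
  "alpha_P6_7": -0.656,
  "alpha_P7_8": -1.63,
  "alpha_P8_9": -1.32,
  "Pmax_Sweet": 4.2,
  "PSweet50": 5.62,
  "Pmax_Cream": 0.466,
  "PCream50": 1.65,
  "IP_Sweet_Cream": -1.9,
  "wIP_Sweet": 39.5,
  "beta_Sugar5": 0.864,
  "beta_Fat3": 3.3,
  "beta_Fat4": 1.5,
  "beta_Fat7": 1.4,
  "omega2_P": 3.2
 },
 "rse_percent": {
  "alpha_S1": 61,
  "alpha_S2_3": 11,
  "alpha_S3_4": 11,
  "alpha_S4_5": 11,
  "alpha_S5_6": 8.6,
  "alpha_S6_7": 8.9,
  "alpha_S7_8": 7.4,
  "alpha_S8_9": 6.0,
  "Smax_Sugar": 4.3,
  "SSugar50": 12,
  "SL_S_Fat": 103,
  "omega2_S": 36,
  "omega2_Smax": 33,
  "alpha_C1": 3,
  "alpha_C2_3": 6.1,
  "alpha_C3_4": 10.2,
  "alpha_C4_5": 11.4,
  "alpha_C5_6": 13.3,
  "alpha_C6_7": 12.7,
  "alpha_C7_8": 14.9,
  "alpha_C8_9": 10.9,
  "SL_C_Fat": 14.4,
  "SL_C_Sugar": 25.1,
  "omega2_C": 38,
  "alpha_P1": 52,
  "alpha_P2_3": 20,
  "alpha_P3_4": 16,
  "alpha_P4_5": 8.8,
  "alpha_P5_6": 90,
  "alpha_P6_7": 14,
  "alpha_P7_8": 37,
  "alpha_P8_9": 12,
  "Pmax_Sweet": 15.5,
  "PSweet50": 43,
  "Pmax_Cream": 60,
  "PCream50": 70,
  "IP_Sweet_Cream": 94,
  "wIP_Sweet": 109,
  "beta_Sugar5": 10,
  "beta_Fat3": 62,
  "beta_Fat4": 17,
  "beta_Fat7": 20,
  "omega2_P": 28
 }
}
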