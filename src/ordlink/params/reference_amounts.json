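{
 "schema_version": 1,
 "variant": "amounts",
 "parameters": {
  "alpha_S1": -0.764,
  "alpha_S2_3": -1.12,
  "alpha_S3_4": -1.00,
  "alpha_S4_5": -0.829,
  "alpha_S5_6": -0.740,
  "alpha_S6_7": -0.797,
  "alpha_S7_8": -0.979,
  "alpha_S8_9": -1.23,
  "Smax_Sugar": 8.32,
  "SSugar50": 7.89,
  "SL_S_Fat": 0.00414,
  "omega2_S": 1.34,
  "omega2_Smax": 0.207,
  "alpha_C1": 1.06,
  "alpha_C2_3": -1.46,
  "alpha_C3_4": -1.06,
  "alpha_C4_5": -0.83,
  "alpha_C5_6": -0.846,
  "alpha_C6_7": -0.902,
  "alpha_C7_8": -1.12,
  "alpha_C8_9": -1.43,
  "SL_C_Fat": 0.186,
  "SL_C_Sugar": 0.049,
  "omega2_C": 4.21,
  "alpha_P1": -0.482,
  "alpha_P2_3": -1.36,
  "alpha_P3_4": -1.2,
  "alpha_P4_5": -0.865,
  "alpha_P5_6": -0.627,
  "alpha_P6_7": -0.661,
  "alpha_P7_8": -1.21,
  "alpha_P8_9": -1.34,
  "Pmax_Sugar": 7.96,
  "PSugar50": 9.86,
  "Pmax_Fat": 2.41,
  "PFat50": 8.7,
  "IP_Sugar_Fat": -2.31,
  "wIP_Sugar": 1.06,
  "beta_Sugar5": 0.928,
  "beta_Fat3": 1.23,
  "beta_Fat4": 1.26,
  "beta_Fat7": 1.19,
  "omega2_P": 4.21
 },
 "rse_percent": {
  "alpha_S1": 70,
  "alpha_S2_3": 10,
  "alpha_S3_4": 13,
  "alpha_S4_5": 9.1,
  "alpha_S5_6": 9.9,
  "alpha_S6_7": 10.7,
  "alpha_S7_8": 8.0,
  "alpha_S8_9": 6.6,
  "Smax_Sugar": 4.9,
  "SSugar50": 14,
  "SL_S_Fat": 40,
  "omega2_S": 35,
  "omega2_Smax": 33,
  "alpha_C1": 62,
  "alpha_C2_3": 6.0,
  "alpha_C3_4": 8.9,
  "alpha_C4_5": 11,
  "alpha_C5_6": 13,
  "alpha_C6_7": 14,
  "alpha_C7_8": 15,
  "alpha_C8_9": 11,
  "SL_C_Fat": 14,
  "SL_C_Sugar": 16,
  "omega2_C": 31,
  "alpha_P1": 165,
  "alpha_P2_3": 11,
  "alpha_P3_4": 14,
  "alpha_P4_5": 6.6,
  "alpha_P5_6": 35,
  "alpha_P6_7": 13,
  "alpha_P7_8": 19,
  "alpha_P8_9": 12,
  "Pmax_Sugar": 105,
  "PSugar50": 120,
  "Pmax_Fat": 61,
  "PFat50": 172,
  "IP_Sugar_Fat": 44,
  "wIP_Sugar": 160,
  "beta_Sugar5": 7.7,
  "beta_Fat3": 12,
  "beta_Fat4": 14,
  "beta_Fat7": 11,
  "omega2_P": 28
 }
}
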