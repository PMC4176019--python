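{
  "comment": "Two published TNNP parameter sets producing near-identical single-cell APs with different underlying current densities, expressed as signed percent changes from the control values.",
  "set1": {
    "g_Na": -11.90, "g_bNa": -3.00, "g_CaL": 0.00, "g_bCa": 7.15,
    "g_to": -25.00, "g_Kr": 31.80, "g_Ks": 28.80, "g_K1": -2.28,
    "g_pK": 7.10, "k_NaK": 3.50, "k_NaCa": -6.68, "a_rel": 21.62,
    "c_rel": -11.90, "V_leak": 58.00, "V_max_up": -6.68, "k_pCa": 1.16
  },
  "set2": {
    "g_Na": 18.47, "g_bNa": 0.00, "g_CaL": -4.50, "g_bCa": -17.74,
    "g_to": 5.90, "g_Kr": -26.70, "g_Ks": 14.80, "g_K1": 42.89,
    "g_pK": -14.90, "k_NaK": 21.60, "k_NaCa": 30.30, "a_rel": -30.00,
    "c_rel": -28.40, "V_leak": 12.20, "V_max_up": -10.90, "k_pCa": 16.14
  }
}
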