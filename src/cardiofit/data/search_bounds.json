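{
  "comment": "Physiologically plausible search ranges for the bounded parameters, compiled from published human ventricular models. The g_to interval is stored sorted; 'as_given' preserves the (transposed) ordering of the compilation it was taken from. The Ca-release ranges are stored in the package's mM/ms convention. b_rel is a fixed SR-release constant, not one of the 16 scalable parameters, hence 'unused'.",
  "bounds": {
    "g_Na":  {"min": 6.93,    "max": 19.3},
    "g_to":  {"min": 0.1728,  "max": 0.384, "as_given": [0.384, 0.1728]},
    "g_Ks":  {"min": 0.027,   "max": 0.539},
    "g_K1":  {"min": 2.4,     "max": 5.405},
    "g_Kr":  {"min": 0.0196,  "max": 0.303},
    "g_CaL": {"min": 0.00008, "max": 0.00029},
    "a_rel": {"min": 0.0109,  "max": 0.0329},
    "c_rel": {"min": 0.0055,  "max": 0.0165}
  },
  "unused": {
    "b_rel": {"min": 0.17, "max": 0.51, "units": "mM"}
  }
}
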