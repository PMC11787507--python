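{
  "protein": "PpcA_Gu",
  "temperature_K": 288.15,
  "g_ox": {"I": -59, "III": -82, "IV": -66},
  "i_redox": {"I-III": 28, "I-IV": 17, "III-IV": 32},
  "g_H": 523,
  "i_bohr": {"I": -52, "III": -47, "IV": -77},
  "standard_errors": {
    "g_ox": {"I": 7, "III": 7, "IV": 8},
    "i_redox": {"I-III": 4, "I-IV": 5, "III-IV": 4},
    "g_H": 10,
    "i_bohr": {"I": 6, "III": 7, "IV": 7}
  }
}
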