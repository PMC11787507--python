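{
  "protein": "PpcB_Gs",
  "temperature_K": 288.15,
  "g_ox": {"I": -150, "III": -166, "IV": -125},
  "i_redox": {"I-III": 17, "I-IV": 8, "III-IV": 32},
  "g_H": 426,
  "i_bohr": {"I": -16, "III": -9, "IV": -38},
  "standard_errors": {
    "g_ox": {"I": 3, "III": 3, "IV": 3},
    "i_redox": {"I-III": 2, "I-IV": 2, "III-IV": 2},
    "g_H": 8,
    "i_bohr": {"I": 4, "III": 4, "IV": 4}
  }
}
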