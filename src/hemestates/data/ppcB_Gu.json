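{
  "protein": "PpcB_Gu",
  "temperature_K": 288.15,
  "g_ox": {"I": -72, "III": -81, "IV": -70},
  "i_redox": {"I-III": 25, "I-IV": 3, "III-IV": 20},
  "g_H": 482,
  "i_bohr": {"I": -2, "III": 9, "IV": -29},
  "standard_errors": {
    "g_ox": {"I": 4, "III": 4, "IV": 5},
    "i_redox": {"I-III": 2, "I-IV": 2, "III-IV": 2},
    "g_H": 9,
    "i_bohr": {"I": 4, "III": 4, "IV": 4}
  }
}
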