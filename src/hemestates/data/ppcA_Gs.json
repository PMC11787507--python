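{
  "protein": "PpcA_Gs",
  "temperature_K": 288.15,
  "g_ox": {"I": -154, "III": -138, "IV": -125},
  "i_redox": {"I-III": 27, "I-IV": 16, "III-IV": 41},
  "g_H": 495,
  "i_bohr": {"I": -32, "III": -31, "IV": -58},
  "standard_errors": {
    "g_ox": {"I": 5, "III": 5, "IV": 5},
    "i_redox": {"I-III": 2, "I-IV": 3, "III-IV": 3},
    "g_H": 8,
    "i_bohr": {"I": 4, "III": 4, "IV": 4}
  }
}
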