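{
  "_comment": "Synthetic heme-methyl probe shifts (ppm). The probe ids follow the heme-methyl naming used for triheme periplasmic cytochromes (2-1CH3 on heme I, 12-1CH3 on heme III, 18-1CH3 on heme IV); the shift values themselves are invented but realistic: diamagnetic reduced-state shifts near 3 ppm, paramagnetic oxidized-state shifts 15-23 ppm, and sub-ppm protonation offsets.",
  "probes": [
    {"id": "2-1CH3-I", "heme": "I", "delta_red": 3.1, "delta_ox_prot": 15.4, "delta_ox_deprot": 15.8},
    {"id": "12-1CH3-III", "heme": "III", "delta_red": 3.4, "delta_ox_prot": 22.8, "delta_ox_deprot": 23.2},
    {"id": "18-1CH3-IV", "heme": "IV", "delta_red": 3.0, "delta_ox_prot": 18.6, "delta_ox_deprot": 19.1}
  ]
}
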