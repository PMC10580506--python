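{
 "meals": [
  {"name": "NPM", "carb_g": 53.0, "protein_g": 32.0, "fat_g": 17.0, "fiber_g": 0.05},
  {"name": "HPFM", "carb_g": 35.0, "protein_g": 49.0, "fat_g": 18.5, "fiber_g": 0.04}
 ]
}
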