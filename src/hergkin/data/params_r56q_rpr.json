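{
  "p1": 0.00766,
  "p2": 0.0699,
  "p3": 0.00144,
  "p4": 0.0143,
  "p5": 0.148,
  "p6": 0.0276,
  "p7": 0.0874,
  "p8": 0.0326,
  "p9": 0.119,
  "p10": 0.0053,
  "p11": 0.086,
  "p12": 0.00798,
  "label": "R56Q+RPR"
}
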