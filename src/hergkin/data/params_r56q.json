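{
  "p1": 0.00649,
  "p2": 0.0697,
  "p3": 0.00735,
  "p4": 1.49e-07,
  "p5": 0.244,
  "p6": 0.0218,
  "p7": 0.081,
  "p8": 0.0198,
  "p9": 0.204,
  "p10": 0.0674,
  "p11": 0.00673,
  "p12": 0.0294,
  "label": "R56Q"
}
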