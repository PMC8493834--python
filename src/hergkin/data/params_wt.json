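{
  "p1": 0.00853,
  "p2": 0.0832,
  "p3": 0.0126,
  "p4": 1.04e-07,
  "p5": 0.27,
  "p6": 0.0158,
  "p7": 0.0767,
  "p8": 0.0225,
  "p9": 0.149,
  "p10": 0.0243,
  "p11": 0.000558,
  "p12": 0.0407,
  "label": "WT"
}
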