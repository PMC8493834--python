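{
  "p1": 0.00667,
  "p2": 0.0752,
  "p3": 0.000271,
  "p4": 0.0244,
  "p5": 0.172,
  "p6": 0.0218,
  "p7": 0.0712,
  "p8": 0.0313,
  "p9": 621.0,
  "p10": 0.00781,
  "p11": 210.0,
  "p12": 0.000503,
  "label": "WT+RPR"
}
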