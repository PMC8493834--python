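{
 "holding_mV": -80.0,
 "steps": [
  [
   -80.0,
   250.0
  ],
  [
   -120.0,
   50.0
  ],
  [
   -80.0,
   400.0
  ],
  [
   40.0,
   1000.0
  ],
  [
   -120.0,
   500.0
  ],
  [
   -80.0,
   500.0
  ],
  [
   -60.0,
   500.0
  ],
  [
   -80.0,
   500.0
  ],
  [
   -40.0,
   500.0
  ],
  [
   -60.0,
   500.0
  ],
  [
   -20.0,
   500.0
  ],
  [
   -40.0,
   500.0
  ],
  [
   0.0,
   500.0
  ],
  [
   -20.0,
   500.0
  ],
  [
   20.0,
   500.0
  ],
  [
   0.0,
   500.0
  ],
  [
   40.0,
   500.0
  ],
  [
   20.0,
   500.0
  ],
  [
   0.0,
   500.0
  ],
  [
   20.0,
   500.0
  ],
  [
   -20.0,
   500.0
  ],
  [
   0.0,
   500.0
  ],
  [
   -40.0,
   500.0
  ],
  [
   -20.0,
   500.0
  ],
  [
   40.0,
   500.0
  ],
  [
   -50.0,
   800.0
  ],
  [
   0.0,
   250.0
  ],
  [
   -80.0,
   700.0
  ],
  [
   0.0,
   250.0
  ],
  [
   -110.0,
   500.0
  ],
  [
   40.0,
   400.0
  ],
  [
   -70.0,
   100.0
  ],
  [
   0.0,
   100.0
  ],
  [
   -70.0,
   400.0
  ],
  [
   0.0,
   100.0
  ],
  [
   -70.0,
   1000.0
  ],
  [
   0.0,
   100.0
  ],
  [
   -100.0,
   100.0
  ],
  [
   0.0,
   100.0
  ],
  [
   -100.0,
   400.0
  ],
  [
   0.0,
   100.0
  ],
  [
   -120.0,
   150.0
  ],
  [
   0.0,
   100.0
  ],
  [
   -120.0,
   500.0
  ],
  [
   -80.0,
   500.0
  ]
 ]
}
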