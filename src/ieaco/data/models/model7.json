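{
 "name": "model7",
 "description": "ZZ model (no marginal effects)",
 "maf_a": 0.5,
 "maf_b": 0.5,
 "declared_prevalence": 0.038,
 "table": [
  [
   0.0,
   0.0,
   0.1
  ],
  [
   0.0,
   0.05,
   0.0
  ],
  [
   0.1,
   0.0,
   0.0
  ]
 ]
}
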