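{
 "name": "model8",
 "description": "XOR model (no marginal effects)",
 "maf_a": 0.5,
 "maf_b": 0.5,
 "declared_prevalence": 0.01,
 "table": [
  [
   0.0,
   0.02,
   0.0
  ],
  [
   0.02,
   0.0,
   0.02
  ],
  [
   0.0,
   0.02,
   0.0
  ]
 ]
}
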