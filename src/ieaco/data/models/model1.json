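{
 "name": "model1",
 "description": "multiplicative model with marginal effects",
 "maf_a": 0.3,
 "maf_b": 0.2,
 "declared_prevalence": 0.1,
 "table": [
  [
   0.087,
   0.087,
   0.087
  ],
  [
   0.087,
   0.146,
   0.19
  ],
  [
   0.087,
   0.19,
   0.247
  ]
 ]
}
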