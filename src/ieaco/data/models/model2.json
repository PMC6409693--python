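{
 "name": "model2",
 "description": "multiplicative model with marginal effects",
 "maf_a": 0.2,
 "maf_b": 0.2,
 "declared_prevalence": 0.1,
 "table": [
  [
   0.092,
   0.092,
   0.092
  ],
  [
   0.092,
   0.145,
   0.181
  ],
  [
   0.092,
   0.181,
   0.227
  ]
 ]
}
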