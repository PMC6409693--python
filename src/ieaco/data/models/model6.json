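{
 "name": "model6",
 "description": "epistasis model without marginal effects",
 "maf_a": 0.4,
 "maf_b": 0.4,
 "declared_prevalence": 0.171,
 "table": [
  [
   0.068,
   0.299,
   0.017
  ],
  [
   0.289,
   0.044,
   0.285
  ],
  [
   0.048,
   0.262,
   0.174
  ]
 ]
}
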