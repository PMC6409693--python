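{
 "name": "model5",
 "description": "epistasis model without marginal effects",
 "maf_a": 0.2,
 "maf_b": 0.2,
 "declared_prevalence": 0.064,
 "table": [
  [
   0.486,
   0.96,
   0.538
  ],
  [
   0.947,
   0.004,
   0.811
  ],
  [
   0.64,
   0.606,
   0.909
  ]
 ]
}
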