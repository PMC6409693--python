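{
 "name": "model3",
 "description": "threshold model with marginal effects",
 "maf_a": 0.05,
 "maf_b": 0.05,
 "declared_prevalence": 0.1,
 "table": [
  [
   0.096,
   0.096,
   0.096
  ],
  [
   0.096,
   0.533,
   0.533
  ],
  [
   0.096,
   0.533,
   0.533
  ]
 ]
}
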