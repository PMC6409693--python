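{
 "name": "model4",
 "description": "threshold model with marginal effects",
 "maf_a": 0.5,
 "maf_b": 0.5,
 "declared_prevalence": 0.1,
 "table": [
  [
   0.052,
   0.052,
   0.052
  ],
  [
   0.052,
   0.137,
   0.137
  ],
  [
   0.052,
   0.137,
   0.137
  ]
 ]
}
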