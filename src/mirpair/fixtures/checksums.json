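{
  "table1_cohort.tsv": "3d6dde4fa6002413597e1cbd8d300d9a29dd51ba2bc0db964eda3fda2fd668fa",
  "table2_differential_expression.tsv": "6469e1ceddd40373c4909f4d226fb401c9caf982e2543380d9be65a4723ea4f8",
  "table3_associations.tsv": "c9522d4ee37f952373f8d2972327ff9345cf7199124092ffb7ed6738635bf6db",
  "table4_seed_summary.tsv": "187e599479ac10b23635b0307ef4f13c342cdc13312c7cb63dc781fc93979999",
  "subgroup_only_genes.tsv": "3ce6c791524d3b8f7f29579b24c9cb50928a35634b4bdccb0765bf4cabb40d0b"
}
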