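[
  {"name": "methylation", "delta_monoisotopic": 14.01565, "delta_average": 14.0266,
   "allowed_targets": ["C", "K", "R", "H", "N", "Q", "E", "D", "N-term"], "max_per_protein": 10},
  {"name": "dimethylation", "delta_monoisotopic": 28.03130, "delta_average": 28.0532,
   "allowed_targets": ["K", "R", "N-term"], "max_per_protein": 10},
  {"name": "trimethylation", "delta_monoisotopic": 42.04695, "delta_average": 42.0797,
   "allowed_targets": ["K", "R", "C", "N-term"], "max_per_protein": 10},
  {"name": "acetylation", "delta_monoisotopic": 42.01057, "delta_average": 42.0367,
   "allowed_targets": ["K", "N-term"], "max_per_protein": 5},
  {"name": "phosphorylation", "delta_monoisotopic": 79.96633, "delta_average": 79.9799,
   "allowed_targets": ["S", "T", "Y"], "max_per_protein": 10},
  {"name": "disulfide", "delta_monoisotopic": -2.01565, "delta_average": -2.0159,
   "allowed_targets": ["C"], "max_per_protein": 5},
  {"name": "initiator-Met-loss", "delta_monoisotopic": -131.04049, "delta_average": -131.1926,
   "allowed_targets": ["N-term"], "max_per_protein": 1}
]
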