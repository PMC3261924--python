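[
  {"label": "all_experiments", "subset": {}, "expected_count": 230},
  {"label": "controlled", "subset": {"controlled": true}, "expected_count": 146},
  {"label": "non_controlled", "subset": {"controlled": false}, "expected_count": 84},
  {"label": "diverged_all", "subset": {"group": "diverged"}, "expected_count": 145},
  {"label": "diverged_controlled", "subset": {"controlled": true, "group": "diverged"}, "expected_count": 105},
  {"label": "diverged_non_controlled", "subset": {"controlled": false, "group": "diverged"}, "expected_count": 40},
  {"label": "close_worm_conserved", "subset": {"stratum": "worm_close_pair", "group": "conserved"}, "expected_count": 34},
  {"label": "close_worm_diverged", "subset": {"stratum": "worm_close_pair", "group": "diverged"}, "expected_count": 30},
  {"label": "obscura_conserved", "subset": {"stratum": "obscura_group", "group": "conserved"}, "expected_count": 9},
  {"label": "obscura_diverged", "subset": {"stratum": "obscura_group", "group": "diverged"}, "expected_count": 12},
  {"label": "caenorhabditis_conservation", "subset": {"stratum": "caenorhabditis", "category": "C1"}, "expected_count": 7},
  {"label": "caenorhabditis_divergence", "subset": {"stratum": "caenorhabditis", "category": ["C2", "C3"]}, "expected_count": 11},
  {"label": "caenorhabditis_misregulation", "subset": {"stratum": "caenorhabditis", "category": ["C4", "C5"]}, "expected_count": 6},
  {"label": "distant_worm_conservation", "subset": {"stratum": "non_caenorhabditis_worm", "category": "NC_I"}, "expected_count": 3},
  {"label": "distant_worm_divergence_misregulation_pool", "subset": {"stratum": "non_caenorhabditis_worm", "category": ["C4", "C5", "NC_II"]}, "expected_count": 20, "note": "printed as 10 + 10 across the divergence and misregulation columns with the same category label (4, 5, II); encoded as two disjoint sets of 10, i.e. one pooled tally of 20 - see methods"},
  {"label": "drosophila_conservation", "subset": {"stratum": "drosophila", "category": "C1"}, "expected_count": 23},
  {"label": "drosophila_divergence", "subset": {"stratum": "drosophila", "category": ["C2", "C3"]}, "expected_count": 39},
  {"label": "drosophila_misregulation", "subset": {"stratum": "drosophila", "category": ["C4", "C5"]}, "expected_count": 22},
  {"label": "non_drosophila_conservation", "subset": {"stratum": "non_drosophila_insect", "category": "C1"}, "expected_count": 11},
  {"label": "non_drosophila_divergence", "subset": {"stratum": "non_drosophila_insect", "category": ["C2", "C3"]}, "expected_count": 6},
  {"label": "non_drosophila_misregulation", "subset": {"stratum": "non_drosophila_insect", "category": ["C4", "C5"]}, "expected_count": 21},
  {"label": "expected_conservation", "subset": {"expectation": "conservation"}, "expected_count": 141},
  {"label": "expected_conservation_diverged", "subset": {"expectation": "conservation", "group": "diverged"}, "expected_count": 72},
  {"label": "expected_divergence", "subset": {"expectation": "divergence"}, "expected_count": 89},
  {"label": "expected_divergence_diverged", "subset": {"expectation": "divergence", "group": "diverged"}, "expected_count": 73},
  {"label": "sophophora_sex_specific", "subset": {"stratum": "sex_specific_sophophora"}, "expected_count": 15},
  {"label": "sophophora_sex_proper", "subset": {"stratum": "sex_specific_sophophora", "swap_sex_proper": true}, "expected_count": 14},
  {"label": "distant_insect_sex_specific", "subset": {"stratum": "sex_specific_distant_insect"}, "expected_count": 15},
  {"label": "distant_insect_sex_proper", "subset": {"stratum": "sex_specific_distant_insect", "swap_sex_proper": true}, "expected_count": 3},
  {"label": "distant_insect_sex_improper_tissue_proper", "subset": {"stratum": "sex_specific_distant_insect", "swap_sex_proper": false, "swap_tissue_proper": true}, "expected_count": 11},
  {"label": "yellow_total", "subset": {"gene": "yellow"}, "expected_count": 26},
  {"label": "yellow_conserved", "subset": {"gene": "yellow", "category": "C1"}, "expected_count": 4},
  {"label": "yellow_trans_only", "subset": {"gene": "yellow", "category": "C2"}, "expected_count": 3},
  {"label": "yellow_cis_only", "subset": {"gene": "yellow", "category": "C3"}, "expected_count": 15},
  {"label": "yellow_cis_trans", "subset": {"gene": "yellow", "category": "C4"}, "expected_count": 4}
]
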