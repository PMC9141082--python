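{
  "species_id": "robinia_pseudoacacia",
  "species_name": "Robinia pseudoacacia L.",
  "two_n": 22,
  "ploidy": 2,
  "class_counts": {"m": 20, "sm": 2},
  "ls_ratio": 3.4821,
  "expected_cytotype": "2B",
  "length_profile": {"longest_um": 4.0},
  "signal_pairs": [
    {"pair_index": 3, "channel": "TAMRA", "arm": "short", "position_fraction": 0.05, "intensity": "strong", "zygosity": "both-homologs"},
    {"pair_index": 5, "channel": "TAMRA", "arm": "long", "position_fraction": 0.95, "intensity": "strong", "zygosity": "both-homologs"},
    {"pair_index": 8, "channel": "TAMRA", "arm": "short", "position_fraction": 0.95, "intensity": "strong", "zygosity": "both-homologs"},
    {"pair_index": 10, "channel": "TAMRA", "arm": "long", "position_fraction": 0.80, "intensity": "strong", "zygosity": "both-homologs"}
  ],
  "notes": "One 5S pair centromeric, three telomeric/proximal-telomeric; eight 5S-bearing chromosomes in total. Pair indices within the karyotype are an encoding choice, not an observed fact."
}
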