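{
  "species_id": "robinia_pseudoacacia_decaisneana",
  "species_name": "Robinia pseudoacacia f. decaisneana (Carr.) Voss",
  "two_n": 22,
  "ploidy": 2,
  "class_counts": {"m": 20, "sm": 2},
  "ls_ratio": 2.0787,
  "expected_cytotype": "1B",
  "length_profile": {"longest_um": 4.0},
  "signal_pairs": [
    {"pair_index": 2, "channel": "TAMRA", "arm": "short", "position_fraction": 0.05, "intensity": "strong", "zygosity": "both-homologs"},
    {"pair_index": 6, "channel": "TAMRA", "arm": "long", "position_fraction": 0.05, "intensity": "strong", "zygosity": "both-homologs"},
    {"pair_index": 8, "channel": "TAMRA", "arm": "long", "position_fraction": 0.95, "intensity": "strong", "zygosity": "both-homologs"},
    {"pair_index": 10, "channel": "TAMRA", "arm": "short", "position_fraction": 0.80, "intensity": "strong", "zygosity": "both-homologs"}
  ],
  "notes": "Two 5S pairs centromeric, two telomeric/proximal-telomeric; eight bearing chromosomes."
}
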