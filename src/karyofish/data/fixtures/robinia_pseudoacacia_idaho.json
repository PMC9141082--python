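{
  "species_id": "robinia_pseudoacacia_idaho",
  "species_name": "Robinia pseudoacacia 'idaho'",
  "two_n": 22,
  "ploidy": 2,
  "class_counts": {"m": 20, "sm": 2},
  "ls_ratio": 1.8997,
  "expected_cytotype": "1A",
  "length_profile": {"longest_um": 4.0},
  "signal_pairs": [
    {"pair_index": 3, "channel": "TAMRA", "arm": "short", "position_fraction": 0.05, "intensity": "strong", "zygosity": "one-homolog"},
    {"pair_index": 3, "channel": "TAMRA", "arm": "short", "position_fraction": 0.05, "intensity": "weak", "zygosity": "one-homolog"},
    {"pair_index": 6, "channel": "TAMRA", "arm": "long", "position_fraction": 0.95, "intensity": "strong", "zygosity": "both-homologs"},
    {"pair_index": 9, "channel": "TAMRA", "arm": "short", "position_fraction": 0.95, "intensity": "strong", "zygosity": "both-homologs"}
  ],
  "notes": "Three 5S pairs, six bearing chromosomes: five strong signals and one weak. Arm positions of the 'idaho' 5S sites are not reported; two telomeric pairs plus one centromeric pair is an ASSUMPTION, with the centromeric pair chosen as the heteromorphic (strong/weak) one."
}
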