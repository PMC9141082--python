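{
  "species_id": "amorpha_fruticosa",
  "species_name": "Amorpha fruticosa L.",
  "two_n": 40,
  "ploidy": 2,
  "class_counts": {"m": 38, "sm": 2},
  "ls_ratio": 3.2058,
  "expected_cytotype": "1B",
  "length_profile": {"longest_um": 4.0},
  "signal_pairs": [
    {"pair_index": 4, "channel": "TAMRA", "arm": "short", "position_fraction": 0.05, "intensity": "strong", "zygosity": "both-homologs"},
    {"pair_index": 12, "channel": "TAMRA", "arm": "long", "position_fraction": 0.05, "intensity": "strong", "zygosity": "both-homologs"}
  ],
  "notes": "Two 5S pairs, both centromeric; four bearing chromosomes."
}
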