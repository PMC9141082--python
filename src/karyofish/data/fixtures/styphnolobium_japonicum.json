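{
  "species_id": "styphnolobium_japonicum",
  "species_name": "Styphnolobium japonicum (L.) Schott",
  "two_n": 28,
  "ploidy": 2,
  "class_counts": {"m": 14, "sm": 12, "st": 2},
  "ls_ratio": 2.6847,
  "expected_cytotype": "2B",
  "length_profile": {"longest_um": 4.0},
  "signal_pairs": [
    {"pair_index": 11, "channel": "TAMRA", "arm": "long", "position_fraction": 0.80, "intensity": "strong", "zygosity": "both-homologs"}
  ],
  "notes": "One 5S pair, proximal-telomeric; two bearing chromosomes."
}
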