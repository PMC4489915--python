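{
  "seed": 11,
  "simulate": {
    "n_tfs": 60,
    "n_background_genes": 150,
    "pathway_sizes": {"ascorbate": 12, "carotenoid": 8, "flavonoid": 6},
    "n_links": {"ascorbate": 6, "carotenoid": 4, "flavonoid": 3},
    "n_archetypes": 8
  },
  "cluster": {"k": 6, "n_init": 4},
  "screen": {
    "selection": {
      "ascorbate": {"min_count": 4, "require_both": false},
      "carotenoid": {"min_count": 3, "require_both": true},
      "flavonoid": {"min_count": 2, "require_both": false}
    }
  }
}
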