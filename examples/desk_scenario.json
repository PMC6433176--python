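{
  "chrom_lengths": {"chr1": 1000000, "chr2": 1000000, "chr3": 1000000,
                    "chr4": 1000000, "chr5": 1000000, "chr6": 1000000,
                    "chr7": 1000000},
  "chloroplast_length": 129000,
  "n_samples_sp1": 16,
  "n_samples_sp2": 16,
  "n_hybrids": 2,
  "n_anc": 10000,
  "n_sp1": 10000,
  "n_sp2": 10000,
  "t_split": 20000,
  "bottleneck_sp1": [14000, 2000, 4000],
  "bottleneck_sp2": [14000, 2000, 4000],
  "migration_rate": 5e-05,
  "migration_window": [0, 5000],
  "mu": 1e-08,
  "mu_chloroplast": 1e-09,
  "r": 1e-08,
  "generation_time": 1.0
}
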