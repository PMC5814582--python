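outdir: demo_run
seed: 7
synthetic:
  n_samples: 40
  n_snp_sites: 1200
  n_genes: 12
  n_duplication_segments: 6
  n_duplications_without_artefact: 1
  chrom_length: 800000
  block_size: 80
  sv_truth_counts: {DEL: 20, INS: 8, INV: 4, TRA_intra: 2}
saturation:
  sizes: [6, 12, 24, 40]
  replicates: 5
imputation: {stride: 10, n_permutations: 3, k: 5, w: 30}
hetdup: {window: 5000, step: 5000, min_sites: 2, min_windows: 2, het_threshold: 0.2, merge_gap: 5000}
ld: {max_lag: 60, bin_width: 20000, threshold: 0.2, window: 50}
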