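# Default synthetic benchmark, written out explicitly.
synthetic:
  seed: 42
  genome_length_bp: 100000
  gc_fraction: 0.45
  n_samples_per_arm: 3
  n_true_variants_per_sample: 300
  n_genes: 2000
  n_deg_up: 100
  n_deg_down: 100
  deg_log2fc: 2.0
  nb_dispersion: 0.05
  n_probes: 3000
  n_hyper: 80
  n_hypo: 80
  delta_beta_planted: 0.30
  n_coupled_hypo_up: 12
  n_coupled_hyper_down: 8
thresholds:
  min_callers: 2
  cluster_window_bp: 10
  cluster_max_in_window: 3
  shared_min_samples: 2
  lfc_threshold: 1.0
  fdr_threshold: 0.05
  dms_delta_threshold: 0.20
  dms_p_threshold: 0.05
  r_cut: -0.6
  corr_p_cut: 0.1
  quadrant_expr_cut: 1.0
  quadrant_meth_cut: 0.1
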