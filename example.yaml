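simulation:
  n_cohorts: 4
  technology_per_cohort: [tenx, tenx, smartseq2, tenx]
  donors_per_cohort_per_group: 8
  cells_per_donor: [120, 180]
  n_genes: 1200
  n_marker_genes_per_celltype: 3
  n_robust_de_genes: 8
  n_private_de_genes_per_cohort: 6
  n_hub_correlated_genes: 4
  hub_t2d_log2fc: 1.0
  frac_outlier_donors: 0.05
  seed: 2
min_cohorts: 3
seed: 2
outdir: example_run
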