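# Example sweep configuration: a merged-data grid over minimum sample
# coverage and clustering threshold, with one deliberately clean
# configuration.  Run with:
#   gbsphylo sweep --config examples/sweep.yaml --out-dir sweep_out

seed: 11

simulation:
  n_taxa: 8
  n_loci: 80
  locus_length: 50
  mu: 0.01
  het: 0.02
  birth_rate: 1.0
  n_replicate_pairs: 2
  background_dropout: 0.05

grid:
  data_types: [merged]
  majority_rule: [false, true]
  min_sample_cov: [2, 5, 10]
  clust_thresholds: ["85", "90", "90_85"]
  min_taxon_cov: [0.15]

# each configuration names its error specification; unlisted labels use the
# default
error_model:
  default: {dropout: 0.10, seq_error: 0.15, het_collapse: 0.05, geno_swap: 0.02}
  per_label:
    merged_nomrb_cov10_c90: {dropout: 0.15, seq_error: 0.03, het_collapse: 0.01, geno_swap: 0.005}
    merged_mrb_cov10_c85: {dropout: 0.05, seq_error: 0.30, het_collapse: 0.10, geno_swap: 0.05, n_loci: 80}

trees:
  enabled: true
  n_bootstrap: 40
  bs_threshold: 70
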