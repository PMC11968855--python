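# Reduced-scale demonstration run: full stage coverage, small sizes.
# All analysis rules (thresholds, filters, matching window, penalty mixing)
# keep their full-scale defaults; only cohort sizes and chain lengths shrink.
seed: 1
cohort:
  n_individuals: 400
  n_cpgs: 600
bayes_ewas:
  burn_in: 1000
  post_burn_iterations: 2000
biomarker:
  n_lambda: 40
seq_filters:
  n_sites: 300
gwas:
  n_individuals: 500
  n_snps: 800
  n_pcs: 10
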