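# ewaspipe

A tested, reusable pipeline for methylation-based analysis of cumulative
smoking exposure:

* **Bayesian mixture EWAS** — spike-at-origin plus four Gaussian slabs over
  per-CpG effects, fit by a single-chain Gibbs sampler (numba-accelerated),
  reporting posterior inclusion probabilities (PIPs), posterior mean effects
  and the posterior of phenotypic variance explained with equal-tailed
  credible intervals.
* **Marginal EWAS** — per-site OLS of methylation on a binary / ordinal /
  continuous smoking phenotype plus age and sex, exact-df t p-values,
  genomic inflation (lambda), tiered hit calling (3.6e-8 genome-wide,
  1e-5 suggestive) and cross-platform hit overlap.
* **Sequencing coverage QC** — bedGraph (targeted short-read) and bedMethyl
  (long-read) ingestion with strand collapsing, then an audited four-step
  site-retention filter: minimum depth-of-coverage mask (DoC >= 2),
  high-coverage removal beyond the 0.99 quantile of per-site mean depth,
  C->T polymorphism BED masking, and a >= 40-samples-at->= 10 (or 5)
  reads rule.
* **Case/control matching** — top pack-years current smokers per sex,
  greedily matched to never-smoker controls by nearest age within sex under
  a hard < 12-month window, with contract re-validation.
* **Elastic-net methylation score** — alpha = 0.5, lambda selected by
  seeded 10-fold cross-validation on a log-spaced path; sparse weights
  stored on the raw beta-value scale with training means for missing-site
  imputation, plus a single-site (one CpG) comparator score.
* **Score evaluation** — incremental R^2 over an age + sex null model,
  Pearson/Spearman correlations, and ROC-AUC / PR-AUC for the
  current-vs-never, current-vs-former and former-vs-never contrasts.
* **GWAS stand-in** — PC covariates, per-SNP OLS scan (5e-8 / 1e-5 tiers),
  Haseman-Elston regression heritability with jackknife SE, and cross-scan
  hit comparison.
* **Synthetic cohorts** — generators for methylation matrices with sparse
  multi-scale effects and exact variance bookkeeping, zero-inflated smoking
  questionnaires (with optional inconsistency injection), overdispersed
  sequencing read counts for two platforms, and Hardy-Weinberg genotypes
  with a polygenic trait. All generators are seed-deterministic, with
  per-operation RNG streams; a `population_seed` lets you draw a fresh
  population under identical ground truth for score-transfer experiments.

## Command line

```sh
# end-to-end demo (deterministic; writes TSVs + manifest.json)
ewaspipe pipeline run --config configs/demo.yaml --out runs/demo

# individual stages
ewaspipe simulate cohort --seed 1 --n 500 --cpgs 1000 --out data/
ewaspipe phenotype --in questionnaire.tsv --out clean.tsv
ewaspipe ewas bayes --methylation resid.tsv --phenotype pheno.tsv \
    --burnin 5000 --iters 10000 --thin 5 --seed 1 --out bayes.tsv
ewaspipe ewas lm --methylation meth.tsv --phenotype pheno.tsv \
    --phenotype-mode binary --out ewas.tsv
ewaspipe seqfilter sample*.bedgraph --dialect bedgraph_panel \
    --min-doc 2 --quantile 0.99 --min-samples 40 --min-reads 10 --out filtered/
ewaspipe match --phenotype clean.tsv --n-per-sex 12 --max-age-diff-days 365 \
    --out pairs.tsv
ewaspipe biomarker train --methylation meth.tsv --phenotype pheno.tsv \
    --alpha 0.5 --folds 10 --seed 1 --out weights.tsv
ewaspipe biomarker score --weights weights.tsv --methylation new_cohort.tsv \
    --out scores.tsv
ewaspipe evaluate --score-file scores.tsv --phenotype-file clean.tsv \
    --out report.json
```

Stage defaults follow the analysis parameterization throughout (Gibbs
burn-in 5000 / 10000 post-burn iterations / thin 5; elastic-net alpha 0.5
with 10 folds; EWAS tiers 3.6e-8 and 1e-5; GWAS tiers 5e-8 and 1e-5;
coverage policy DoC 2 / 0.99 quantile / 40 samples / 10 or 5 reads;
12-month matching window), and every default is echoed into the run
manifest.

## Layout

```
src/ewaspipe/
  synthetic.py   # cohort / coverage / genotype simulators + truth records
  phenotype.py   # pack years, record QC, phenotype transform, residualization
  bayes.py       # spike + Gaussian-mixture Gibbs sampler, PIPs, credible intervals
  marginal.py    # per-site OLS EWAS, genomic inflation, tiers, overlap
  seqfilters.py  # bedGraph/bedMethyl IO, coverage filter pipeline + audit
  matching.py    # case selection, greedy nearest-age matching, validation
  biomarker.py   # elastic-net and single-site scores, projection with imputation
  evaluate.py    # incremental R^2, correlations, ROC-AUC, PR-AUC
  gwas.py        # PCs, association scan, HE-regression h2, scan comparison
  pipeline.py    # stage orchestration, config, deterministic manifests
  cli.py         # click-based command line
```
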