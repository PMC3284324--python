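# outbredgwas

Association mapping toolkit for outbred populations. It implements a full
genome-wide association workflow for a modest-size outbred cohort (hundreds
of samples, tens of thousands of SNPs):

- **Synthetic populations** (`outbredgwas.synth`) — founder-based outbred
  simulator with Poisson crossovers, a drift bottleneck that produces
  realistic LD decay, additive-QTL + polygenic + residual traits, a
  zero-inflated skewed trait, and ground-truth records for recovery tests.
  Presets: `nmri-like` (288 samples, structured kinship, ~1 Mb LD radius)
  and `tiny` (64 samples, 500 SNPs) for tests.
- **Genotype/phenotype QC** (`outbredgwas.qc`) — MAF / Hardy-Weinberg
  chi-square / missingness filters (strict comparisons: MAF > 2%,
  chi2 < 20, missing < 40%), identical-SNP collapsing within 2 Mb,
  frequency-sampling imputation, duplicate-sample removal, `log(x+1)`
  transforms and repeated-reading trimming.
- **Population structure** (`outbredgwas.structure`) — identity-by-state
  kinship, pairwise identity with duplicate flagging, windowed genotypic
  r², LOWESS-smoothed median LD decay with a 0.5-crossing decay radius,
  symmetric Shannon entropy per SNP and in 4-Mb windows, hierarchical
  clustering of samples.
- **Genome scans** (`outbredgwas.scan`) — additive trend test (1 df),
  genotype-factor ANOVA (2 df), and a kinship mixed-model trend test with
  REML variance components (spectral decomposition + 1-D profiling over
  sigma_e2/sigma_g2; whiten-once default, per-SNP refit optional),
  conditional scans with covariate SNPs, nested-model R² decompositions.
- **Significance thresholds** (`outbredgwas.significance`) — the
  kinship-preserving structured permutation (van der Waerden transform,
  REML fit, multivariate-normal rank matching), per-replicate scan maxima,
  maximum-likelihood GEV tail fit with quantile thresholds, plain free
  permutation for comparison, and an empirical-quantile fallback.
- **Multilocus models** (`outbredgwas.multilocus`) — bootstrap forward
  stepwise regression and resample model inclusion probabilities (RMIP)
  with a ±w bp window rule.
- **Mapping precision** (`outbredgwas.precision`) — causal-SNP injection,
  leave-target-out rescans, tie-median peak distances, cross-chromosome
  exclusion, and distance-quantile summaries.

## CLI

Every stage is exposed as a subcommand of `outbredgwas`:

```sh
outbredgwas simulate --preset nmri-like --seed 1 --out-prefix out/pop
outbredgwas qc --genotypes out/pop.ped --out-prefix out/qc
outbredgwas kinship --genotypes out/qc.genotypes.tsv --out out/kinship.tsv
outbredgwas ld --genotypes out/qc.genotypes.tsv --out out/ld.tsv
outbredgwas entropy --genotypes out/qc.genotypes.tsv --out out/entropy.tsv
outbredgwas scan --genotypes out/qc.genotypes.tsv --phenotypes out/pop.pheno.tsv \
    --trait trait --test mixed --out out/scan.tsv
outbredgwas thresholds --genotypes out/qc.genotypes.tsv --phenotypes out/pop.pheno.tsv \
    --trait trait --method structured --test mixed --reps 100 --out out/thr.json
outbredgwas rmip --genotypes out/qc.genotypes.tsv --phenotypes out/pop.pheno.tsv \
    --trait trait --reps 100 --window-mb 1 --out out/rmip.tsv
outbredgwas precision --genotypes out/qc.genotypes.tsv --sims 200 --out-prefix out/prec
outbredgwas run-all --config pipeline.yaml
```

`run-all` reads a YAML file matching `outbredgwas.pipeline.PipelineConfig`
(simulation preset or genotype/phenotype paths, QC thresholds, tests,
threshold method/reps, RMIP and precision parameters, root seed, output
directory) and writes every stage artifact plus a `manifest.json` that makes
the run exactly reproducible.

Genotype inputs: PLINK-style `.ped`/`.map`, a genotype TSV
(`snp_id  chrom  pos  <sample columns>` with dosages 0/1/2 or NA), or VCF.

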