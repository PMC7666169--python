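# rohid

Runs-of-homozygosity (ROH) calling, genomic inbreeding coefficients, and
inbreeding-depression (ID) regression for quantitative traits — with a
synthetic-cohort generator that plants known autozygosity and directional
dominance so every stage can be validated against ground truth.

## What it does

- **`rohid.synthetic`** — simulates autosomal SNP genotypes with
  per-individual homozygous-by-descent (HBD) segments at a controlled
  inbreeding level, Hardy–Weinberg genotypes elsewhere, and traits built
  from a locus-level additive + directional-dominance model
  (closed-form mean change under inbreeding: `-2F Σ d_i p_i q_i`).
- **`rohid.io`** — PLINK 1 `.bed/.bim/.fam` and VCF 4.2 (GT) readers and
  writers, plus cohort QC: sample call rate > 0.98, variant missingness
  ≤ 0.01, MAF ≥ 0.01, exact Hardy–Weinberg test p ≥ 5e-4.
- **`rohid.roh`** — sliding-window ROH detection with the standard
  `--homozyg` parameterization (window 30 SNPs, ≤1 het, ≤5 missing, hit
  threshold 0.05, min 30 SNPs / 300 kb, density ≤ 30 kb/SNP, gap split at
  1 Mb; no LD pruning), plus a literal brute-force oracle used in tests.
  The hit-fraction denominator near chromosome ends counts only windows
  that actually exist (truncation) — this is the main dialect choice.
- **`rohid.metrics`** — per-sample `F_ROH` (ROH strictly > 1.5 Mb over a
  3 Gb genome by default), `F_GRM` (Fhat3 over MAF > 0.05 loci),
  `F_outsideROH` (excess homozygosity outside called ROH), the
  frequency-standardized GRM, and genotype PCs.
- **`rohid.models`** — two-step ID estimation: REML mixed model removes
  fixed covariates and the polygenic background (residuals subtract the
  BLUP), then OLS of residuals on `F_ROH` (± `F_outsideROH`), bivariate
  `F_ROH + F_GRM` conditioning, sex/luminosity-stratified fits with
  within-stratum standardization, ANCOVA-style stratum comparison and
  Mann–Whitney comparison of standardized effect sets.
- **`rohid.windows`** — regional scan: 3-Mb genome tiling, per-window ROH
  fraction, per-window regression with Bonferroni control over tested
  windows, QQ calibration output.
- **`rohid.pipeline` / `rohid.cli`** — one-config orchestration with a
  reproducibility manifest.

## CLI

```bash
rohid simulate --config sim.yaml --out sim/          # synthetic cohort
rohid qc --plink-prefix sim/cohort --out qc/
rohid call-roh --plink-prefix qc/qc --out roh.tsv
rohid inbreeding --plink-prefix qc/qc --roh roh.tsv --out profile.tsv
rohid run-all --config pipeline.yaml --out run/      # full chain
rohid report --out-dir run/
```

A minimal `pipeline.yaml`:

```yaml
seed: 1
simulate:
  n_individuals: 2000
  chromosome_lengths: [60000000, 40000000]
  snp_spacing_bp: 10000
  f_target_law: [uniform, 0.0, 0.1]
  n_causal_loci: 100
  dominance_mean_d: 0.5
traits: [trait]
strata: [sex]
genome_length_bp: 100000000
```

## Conventions

- Genotype codes are 0/1/2 counts of the B allele (PLINK A1 / VCF ALT),
  −1 for missing; positions are 1-based inclusive internally, 0-based
  half-open in BED exports.
- `F_ROH` uses strictly-greater length thresholds and a fixed 3 Gb
  denominator by default (configurable to the covered genome length).
- All randomness flows from a single seed via fixed per-stage derivation;
  reruns are bit-identical.
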