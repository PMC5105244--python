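# csfqtl

Quantitative-trait genetics of cerebrospinal-fluid (CSF) biomarkers: a tested
pipeline for finding the genetic regulators of a CSF protein level and for
using that genetic information to sharpen the protein's value as a biomarker.

## The problem

CSF levels of YKL-40 (the chitinase-3-like 1 protein, *CHI3L1*) rise in
Alzheimer's disease and correlate strongly with phosphorylated tau
(ptau181), but a large share of their inter-individual variability is
genetic rather than disease-driven.  If a single common variant explains a
sizeable fraction of the biomarker's variance yet has nothing to do with
disease status, removing that variant's contribution should *strengthen* the
biomarker's correlation with disease-linked analytes.  `csfqtl` implements
that whole argument as code:

1. **Genotype QC** — sample/variant call-rate filters, minor-allele-frequency
   floor, an exact Hardy–Weinberg test, duplicate detection by genotype
   concordance, and EIGENSTRAT-style principal components
   (g − 2p)/√(2p(1−p)) for population structure.
2. **GWAS** — per-variant additive-model OLS of the log-transformed,
   standardized analyte on allele counts with age, gender, batch and PC
   covariates: y = α + βg + γᵀc + ε, two-sided t-tests, genome-wide
   (p < 5×10⁻⁸) and suggestive (p < 1×10⁻⁵) classes, the genomic inflation
   factor λ = median(χ²)/0.4549, and conditional analysis on an index SNP.
3. **Variance decomposition** — ΔR² of nested linear models: R²(covariates +
   SNP) − R²(covariates).
4. **Genetic adjustment** — externally studentized residuals of
   y ~ intercept + allele counts, i.e. the biomarker with its genetic
   component removed.  For a genetic component orthogonal to a target
   analyte this rescales the correlation to r/√(1 − R²_G).
5. **Correlation comparison** — Meng's Z-test for two dependent overlapping
   correlations (target↔unadjusted vs target↔adjusted), with a 95% CI on the
   Fisher-z difference scale.
6. **Case/control** — IRLS logistic regression of cognitive status on the
   (adjusted or unadjusted) biomarker with covariates.

Because cohort-level CSF + genotype data are not publicly deposited, the
package ships a first-class synthetic-cohort generator whose defaults encode
the study conditions the analysis assumes (379 samples; one causal SNP at
MAF 0.244 explaining 12.74% of log-biomarker variance; covariates explaining
14.89%; a latent factor giving a biomarker–ptau correlation of 0.52 with the
genetic component independent of ptau; 21% cases with elevated biomarker).
Every stage is tested against that known generative structure.

## Worked example

```bash
cat > config.yaml <<EOF
seed: 7
simulate:
  n_samples: 379
  n_null_variants: 150
EOF
csfqtl run-all --config config.yaml --outdir out
```

prints (stage logs on stderr, summary on stdout):

```
top variant: causal_1 p=2.13e-15 lambda=0.979
compare ptau181: r 0.469 -> 0.509 p=0.01426 (reject)
compare tau: r 0.435 -> 0.471 p=0.02778 (reject)
compare abeta42: r 0.051 -> 0.038 p=0.4735 (retain)
compare tau_abeta_ratio: r 0.339 -> 0.384 p=0.009638 (reject)
```

Reading this: the causal SNP is recovered at genome-wide significance with a
well-calibrated scan (λ ≈ 1); its ΔR² is written to the manifest
(`r2_variant` ≈ 0.128 here against the generative 0.1274); removing its
effect raises the biomarker's correlation with the latent-driven analytes
(ptau181, tau, and the tau/Aβ42 ratio — "reject" means the correlation change
is significant at α = 0.05) and leaves the independent analyte (Aβ42)
untouched ("retain").  `out/` contains every stage table (association.tsv,
comparisons.tsv, status_tests.tsv, …) plus `manifest.json` with SHA-256
digests for reproducibility; rerunning the same config reproduces identical
digests.

Each stage is also available as its own subcommand (`simulate`, `qc`, `pca`,
`gwas`, `adjust`, `compare`, `status-test`) and as plain library functions
(`csfqtl.run_gwas`, `csfqtl.meng_test`, …).

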