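# Methods

## Overview

`csfqtl` treats a CSF analyte level as a quantitative trait.  The analysis
chain is: log-transform and standardize the analyte; scan genotyped variants
one at a time under an additive model with demographic covariates and
population-structure principal components; quantify the top locus's
incremental variance (ΔR² of nested models); residualize the analyte on that
locus; and ask, with a test that respects the dependence structure, whether
the residualized analyte correlates more strongly with other CSF analytes
than the raw one did.  A logistic model relates the (adjusted or unadjusted)
analyte to case/control status.

## Generative model of the synthetic cohort

The generator produces the study conditions the analysis assumes, on the
standardized log-biomarker scale (total variance 1):

Y = √c² · W + β_g (G − 2p) + γL + s(D − π) + ε

* **G** — causal allele count, Binomial(2, p) under Hardy–Weinberg with
  p = 0.244 by default; β_g is solved so the SNP explains exactly
  `target_snp_r2` (default 0.1274) of Var(Y):
  β_g = √(r²/(1−r²)) · σ_rest/√(2p(1−p)).
* **W** — unit-variance equal-weight combination of standardized age
  (N(70.86, 8.80²) years), gender (Bernoulli, female fraction 231/379,
  coded 0/1) and batch (uniform over `n_batches`, default 3, entering the
  generative model through a linear batch score and the analysis through
  indicator columns, which span that score).  The covariate share c² defaults
  to 0.1489.
* **L** — standard-normal latent "neurodegeneration" factor.  Both the
  biomarker (loading γ = sign(ρ)√|ρ|) and log-ptau/log-tau (loading √|ρ|)
  load on it, so corr(Y, log ptau) = ρ exactly (default ρ = 0.52), while G
  never enters ptau: the genetic component is independent of the target
  analyte by construction.
* **D** — case indicator, Bernoulli(π = 0.2111); the shift s (default 0.68
  SD) is the log-scale case/control mean difference implied by the emulated
  cohort's printed means (≈366 vs ≈290 ng/mL over a log-SD of ≈0.343).
* **ε** — Gaussian noise absorbing the remaining variance; a configuration
  whose components sum to ≥ 1 is rejected as an inconsistent budget.

Analytes are exponentiated onto assay scales (biomarker ~307 ng/mL, ptau ~61,
tau ~320, Aβ42 ~500 pg/mL; Aβ42 is independent noise and the tau/Aβ42 ratio
is computed from its parts).  Because generation happens on the log scale,
the pipeline's log-standardization linearizes the model exactly and every
configured fraction is an exact population quantity — which is what makes
closed-form checks (ΔR² recovery, the r/√(1−R²_G) adjustment limit) sharp.

Null variants draw MAFs uniformly from `null_maf_range` (default
(0.05, 0.5)); the lower default sits above the 0.02 QC floor so a clean
simulated cohort passes QC untouched.  There is no linkage disequilibrium
between variants, no dosage uncertainty, and no longitudinal structure —
passing tests therefore certify the statistical machinery, not robustness to
LD-induced confounding or imputation noise in real array data.

## Quality control

Sample call-rate filtering (default ≥ 0.98, exclusion when *below* the
threshold) precedes variant filters, the common convention when an order is
not dictated.  Variant filters: call rate ≥ 0.98, MAF ≥ 0.02, exact
Hardy–Weinberg p ≥ 10⁻⁶.  The HWE test is the standard exact conditional
(non-mid-p) formulation: given allele counts, the probability of every
feasible heterozygote count is accumulated by a ratio recurrence outward
from the modal count (numerically safe for any table size), and the p-value
sums configurations no more probable than the observed one, with a 10⁻¹⁰
relative slack on the comparison so exact ties are included regardless of
floating-point noise.

Duplicate detection uses pairwise genotype concordance (fraction of sites,
non-missing in both, with identical calls; flag at ≥ 0.95) rather than
method-of-moments IBD: duplicates and near-duplicates are the QC target and
concordance finds them without the full kinship machinery.  This is a
deliberate simplification; it does not estimate relatedness coefficients.

PCA standardizes each variant column by its observed allele frequency,
mean-imputes missing calls (only for PCA — association never imputes), drops
monomorphic variants, and returns orthonormal sample eigenvectors with
descending eigenvalues; component signs are fixed by making each score
vector's largest-magnitude entry positive, so results are reproducible and
invariant (up to that convention) to variant order.

## Association

Each variant is fit by OLS on its own complete cases (samples missing that
genotype are dropped for that variant only; no dosage imputation).  For
variants with no missingness the scan uses the Frisch–Waugh–Lovell route —
residualize y and G on the covariate block once via QR, then per-variant
scalar regression — which is algebraically identical to the full OLS and
makes a 50,000-variant scan a few matrix products.  p-values are two-sided
from the t distribution with n − p df (not the normal approximation; at
n ≈ 379 the difference is visible).  Effects are reported per copy of the
counted allele, the VCF ALT, recorded explicitly in the output (`A1`) so
signs are unambiguous.  Monomorphic or covariate-collinear variants yield NA
rows with a reason code.  Ties in p are broken by (chromosome, position)
when sorting, so "top SNP" selection is deterministic.

λ is median(χ²₁-quantile of 1 − p)/0.45494; the conditional scan appends the
index variant's counts to the covariates and reports the index row as NA
(`conditioned_on`).

## Adjustment

ΔR² is the difference of plain (not adjusted) R² between the
covariates+variant and covariates-only models on the common complete-case
set; nesting guarantees ΔR² ≥ 0 up to roundoff, and tiny negatives are
clipped at 0 (an error is raised beyond 10⁻⁹).  Note the sample R² of a
k-predictor model overshoots its population value by roughly k(1−R²)/n —
at n = 379 with four covariate columns about +0.009 — which is a property of
the estimator the package reports, not a bug; the parameter-recovery test
bands account for it.

The genetic adjustment regresses the log-standardized analyte on intercept +
allele counts **only** (covariate-augmented adjustment is available behind a
flag), and returns *externally* studentized residuals
e_i/(s₍ᵢ₎√(1−h_ii)) with the leave-one-out variance s₍ᵢ₎² — the common
statistical-software default; internal studentization is a flag, and the two
differ negligibly at cohort scale (property-tested).  Samples missing the
genotype keep missing adjusted values.

Mechanism: for a genetic component orthogonal to a target analyte, removing
a variance fraction R²_G from Y rescales corr(Y, T) by 1/√(1−R²_G).  At the
default architecture this predicts a median correlation increase of
0.52(1/√(1−0.1274) − 1) ≈ 0.037 — the quantity the acceptance tests verify
by Monte Carlo.

## Correlation comparison

Meng, Rosenthal & Rubin's Z for two dependent overlapping correlations:
with z = arctanh(r), r̄² = (r²_jk + r²_jh)/2, f = min(1, (1−r_kh)/(2(1−r̄²)))
(capped at 1 per the original formulation, preventing h < 0), and
h = (1−f r̄²)/(1−r̄²),

Z = (z_jk − z_jh) √((n−3)/(2(1−r_kh)h)).

The 95% CI is reported on the Fisher-z difference scale (where the method is
defined; a back-transformed interval is easy to add but not the default),
and the null is retained iff the interval includes 0 — decision and p are
consistent by construction.  All three correlations use one common
complete-case n, as the formula assumes.  The correlation triple is checked
for positive semidefiniteness; |r_jk| = 1 or |r_jh| = 1 are errors (the
transform diverges), while r_kh = 1 with r_jk = r_jh returns the degenerate
Z = 0, p = 1, retain result (comparing a variable with itself).  Steiger/
Hittner variants are not implemented; reported results across such models
are known to be comparable and one well-tested route keeps scope tight.

## Case/control model

Status (case = cognitively impaired) is regressed on the log-standardized
analyte (raw/pre-adjusted columns via flag) plus age, gender and batch
indicators by IRLS with step-halving, which makes the deviance monotone
non-increasing; convergence is a 10⁻⁸ coefficient-change tolerance within 50
iterations.  Complete or quasi-complete separation is detected via diverging
linear predictors (|Xβ| > 30) and raised as an error — no Firth correction,
because at these cohort sizes separation is a data problem worth surfacing
rather than smoothing over.

## Pipeline

The YAML config (seed mandatory) drives simulate/load → QC → PCA → GWAS →
top-variant selection → ΔR² → adjustment → Meng comparisons → status tests.
The global seed is expanded into per-stage substreams (SeedSequence spawning)
so stages are individually reproducible.  Every stage output is written
atomically (`.partial` until complete) and digested (SHA-256) into
`manifest.json`; the manifest contains no timestamps, so identical configs
reproduce byte-identical manifests.  If no variant reaches genome-wide
significance the adjustment stages are skipped with a warning unless
`force_adjust` is set, in which case the top (non-genome-wide) variant is
used.

## Problem sizes used in tests

Monte-Carlo test sizes were chosen so each check's sampling error sits well
inside its assertion band: 50,000 variants for the λ calibration
(SE(λ) ≈ 0.010), 500 replicates for ΔR²/covariate-R² recovery
(SE ≈ 0.0015) and for the adjustment-direction check, 2,000 replicates for
Meng type-I calibration (2·SE ≈ 0.0097), 600 for the logistic null, 200 for
genome-wide power (expected ≈ 0.97 against the ≥ 0.95 bound), and 100 for
the conditional-scan check.

## Known limitations

* No LD, imputation, kinship estimation beyond duplicate flagging, or
  X-chromosome handling; the simulator is autosomal and unlinked.
* Per-variant complete-case association assumes genotype missingness is
  noninformative.
* The Meng comparison assumes joint normality of the three variables; the
  log transform makes this exact for simulated data and approximate for
  real assay data.
* The case/control shift enters as a mean shift on the log scale, not a
  liability-threshold model: only the direction and magnitude of the
  case–control difference is emulated.
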