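"""Synthetic genotype/phenotype cohorts for CSF-biomarker genetics.

The generator emulates a cross-sectional memory-clinic cohort in which one
common variant regulates the CSF level of a secreted glycoprotein (a YKL-40
analogue), demographic covariates (age, gender, assay batch) explain a further
share of the variance, and a latent neurodegeneration factor couples the
biomarker to phosphorylated tau — while the genetic component is, by
construction, independent of tau.  Everything downstream (QC, GWAS, variance
decomposition, genetic adjustment, correlation comparison) is testable against
this known generative structure.

All analytes are generated on the natural-log scale and exponentiated, so the
pipeline's "log-transform then standardize" step linearizes them exactly and
every configured variance fraction is an exact population quantity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "ANALYTE_COLUMNS",
    "simulate_genotypes",
    "solve_effect_size",
    "simulate_cohort",
    "validate_phenotypes",
]

#: analyte columns of a phenotype table, in canonical order
ANALYTE_COLUMNS = ("ykl40", "ptau181", "tau", "abeta42", "tau_abeta_ratio")

# Log-scale location/scale used to map standardized latent analyte values onto
# realistic assay units (biomarker ~307 ng/mL with CV ~0.35; ptau ~61 pg/mL;
# tau ~320 pg/mL; Abeta42 ~500 pg/mL).
_ANALYTE_SCALES = {
    "ykl40": (5.7276, 0.343),
    "ptau181": (4.1109, 0.40),
    "tau": (5.7683, 0.45),
    "abeta42": (6.2146, 0.30),
}

# Population parameters for covariate generation (age in years; gender coded
# 0 = male, 1 = female with the cohort's observed female fraction).
_AGE_MEAN, _AGE_SD = 70.86, 8.80
_FEMALE_FRACTION = 231.0 / 379.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for :func:`simulate_cohort`.

    Defaults are the emulated study's conditions: 379 samples, one causal SNP
    at MAF 0.244 explaining 12.74% of log-biomarker variance, covariates
    explaining 14.89%, a latent factor producing a biomarker-ptau correlation
    of 0.52 with no genetic contribution to ptau, and ~21% cases whose
    log-biomarker is shifted upward by 0.68 SD.
    """

    seed: int
    n_samples: int = 379
    n_null_variants: int = 200
    causal_maf: float = 0.244
    null_maf_range: tuple[float, float] = (0.05, 0.5)
    target_snp_r2: float = 0.1274
    covariate_r2: float = 0.1489
    latent_corr: float = 0.52
    case_fraction: float = 0.2111
    case_shift: float = 0.68
    n_batches: int = 3
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_null_variants < 0 or self.n_batches < 1:
            raise ValueError("n_samples, n_null_variants, n_batches must be positive counts")
        if not (0.0 < self.causal_maf <= 0.5):
            raise ValueError(f"causal_maf must be in (0, 0.5], got {self.causal_maf}")
        lo, hi = self.null_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"null_maf_range must satisfy 0 < low <= high <= 0.5, got {self.null_maf_range}")
        if lo < 0.02:
            raise ValueError("null_maf_range low must be >= 0.02 (study MAF floor)")
        for name in ("target_snp_r2", "covariate_r2"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.target_snp_r2 + self.covariate_r2 >= 1.0:
            raise ValueError("target_snp_r2 + covariate_r2 must be < 1")
        if not (-1.0 < self.latent_corr < 1.0):
            raise ValueError(f"latent_corr must be in (-1, 1), got {self.latent_corr}")
        if not (0.0 <= self.case_fraction < 1.0):
            raise ValueError(f"case_fraction must be in [0, 1), got {self.case_fraction}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self._noise_variance() <= 0.0:
            raise ValueError(
                "inconsistent variance budget: SNP R2 + covariate R2 + |latent_corr| "
                "+ case-shift variance must sum to < 1"
            )

    def _case_variance(self) -> float:
        return self.case_shift**2 * self.case_fraction * (1.0 - self.case_fraction)

    def _noise_variance(self) -> float:
        return 1.0 - (
            self.target_snp_r2
            + self.covariate_r2
            + abs(self.latent_corr)
            + self._case_variance()
        )


@dataclass
class GenotypeMatrix:
    """Samples x variants additive allele-count matrix.

    ``counts`` is a float array with entries in {0, 1, 2} (copies of the
    counted allele, the VCF ALT) and NaN for missing calls.  ``variants`` is a
    DataFrame with columns chrom, pos, id, ref, alt, counted_allele.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        vals = self.counts[~np.isnan(self.counts)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype counts must be in {0, 1, 2} or missing")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        ids = self.variants["id"]
        if ids.duplicated().any():
            raise ValueError("variant ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            avail = ", ".join(self.variants["id"].head(20))
            raise KeyError(
                f"variant {variant_id!r} not found; available ids include: {avail}"
                + (" ..." if self.n_variants > 20 else "")
            )
        return int(np.flatnonzero(self.variants["id"].to_numpy() == variant_id)[0])

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        ids = [s for s, k in zip(self.sample_ids, keep) if k] if keep.dtype == bool else [
            self.sample_ids[i] for i in keep
        ]
        return GenotypeMatrix(ids, self.variants.reset_index(drop=True), self.counts[keep])

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            self.variants.loc[keep].reset_index(drop=True),
            self.counts[:, keep],
        )


def _variant_meta(mafs: np.ndarray, causal_index: int | None = None) -> pd.DataFrame:
    """Invent variant metadata: variants cycle over autosomes at spaced positions."""
    m = len(mafs)
    chroms = [str(1 + (j % 22)) for j in range(m)]
    pos = [100_000 + 50_000 * (j // 22 + 1) for j in range(m)]
    ids = [f"var{j + 1:05d}" for j in range(m)]
    if causal_index is not None:
        ids[causal_index] = "causal_1"
        chroms[causal_index] = "1"
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "id": ids,
            "ref": "A",
            "alt": "G",
            "counted_allele": "G",
        }
    )


def simulate_genotypes(
    n_samples: int,
    mafs,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Draw unlinked genotypes under Hardy-Weinberg proportions.

    Each variant's count is two independent Bernoulli(alt-frequency) allele
    draws, i.e. Binomial(2, maf); missing calls are masked uniformly at
    ``missing_rate``.  The counted allele is the ALT allele.
    """
    mafs = np.asarray(mafs, dtype=float)
    if mafs.ndim != 1 or mafs.size == 0:
        raise ValueError("mafs must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(mafs)) or np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("all mafs must be finite and in (0, 0.5]")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.binomial(2, mafs, size=(n_samples, mafs.size)).astype(float)
    if missing_rate > 0:
        counts[rng.random(counts.shape) < missing_rate] = np.nan
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    return GenotypeMatrix(sample_ids, _variant_meta(mafs), counts)


def solve_effect_size(target_r2: float, maf: float, residual_sd: float = 1.0) -> float:
    """Per-allele effect beta such that the variant explains ``target_r2``.

    Under HWE the allele count has variance 2p(1-p), so beta solves
    beta^2 * 2p(1-p) / (beta^2 * 2p(1-p) + residual_sd^2) = target_r2.
    """
    if not (0.0 <= target_r2 < 1.0):
        raise ValueError(f"target_r2 must be in [0, 1), got {target_r2}")
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    if residual_sd <= 0:
        raise ValueError("residual_sd must be positive")
    var_g = 2.0 * maf * (1.0 - maf)
    return residual_sd * np.sqrt(target_r2 / ((1.0 - target_r2) * var_g))


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Generate a full cohort: genotypes plus a phenotype/covariate table.

    Structural model on the standardized log-biomarker scale (total variance 1):

        Y = sqrt(c2) * W  +  beta_g * (G - 2p)  +  gamma * L
            + case_shift * (status - pi)  +  eps

    with W a unit-variance combination of standardized age, gender and batch,
    G the causal allele count, L a standard-normal latent factor shared with
    ptau (and tau), and status ~ Bernoulli(pi).  ptau and tau load on L only
    (no genetic term), Abeta42 is independent noise, and the tau/Abeta42 ratio
    is computed from its parts.  gamma and the ptau loading are both
    sqrt(|latent_corr|) (sign on gamma), making corr(Y, log ptau) exactly
    ``latent_corr`` in the population.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_g, rng_c, rng_p = (np.random.default_rng(s) for s in ss.spawn(3))
    n = cfg.n_samples

    # --- genotypes: causal variant first, then null variants -----------------
    null_mafs = rng_g.uniform(*cfg.null_maf_range, size=cfg.n_null_variants)
    mafs = np.concatenate([[cfg.causal_maf], null_mafs])
    raw_counts = rng_g.binomial(2, mafs, size=(n, mafs.size)).astype(float)
    g_causal = raw_counts[:, 0].copy()  # phenotype uses pre-masking calls

    counts = raw_counts
    if cfg.missing_rate > 0:
        counts = raw_counts.copy()
        counts[rng_g.random(counts.shape) < cfg.missing_rate] = np.nan
    meta = _variant_meta(mafs, causal_index=0)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    geno = GenotypeMatrix(sample_ids, meta, counts)

    # --- covariates ----------------------------------------------------------
    age = rng_c.normal(_AGE_MEAN, _AGE_SD, size=n)
    gender = rng_c.binomial(1, _FEMALE_FRACTION, size=n).astype(float)
    batch = rng_c.integers(0, cfg.n_batches, size=n).astype(float)

    z_parts = [
        (age - _AGE_MEAN) / _AGE_SD,
        (gender - _FEMALE_FRACTION) / np.sqrt(_FEMALE_FRACTION * (1 - _FEMALE_FRACTION)),
    ]
    if cfg.n_batches > 1:
        k = cfg.n_batches
        batch_effect = batch - (k - 1) / 2.0
        z_parts.append(batch_effect / np.sqrt((k * k - 1) / 12.0))
    w = sum(z_parts) / np.sqrt(len(z_parts))
    cov_term = np.sqrt(cfg.covariate_r2) * w

    # --- structural phenotype model ------------------------------------------
    beta_g = solve_effect_size(cfg.target_snp_r2, cfg.causal_maf, np.sqrt(1.0 - cfg.target_snp_r2))
    latent = rng_p.standard_normal(n)
    status = rng_p.binomial(1, cfg.case_fraction, size=n)
    gamma = np.sign(cfg.latent_corr) * np.sqrt(abs(cfg.latent_corr))
    noise_sd = np.sqrt(cfg._noise_variance())

    y = (
        cov_term
        + beta_g * (g_causal - 2.0 * cfg.causal_maf)
        + gamma * latent
        + cfg.case_shift * (status - cfg.case_fraction)
        + noise_sd * rng_p.standard_normal(n)
    )

    load = np.sqrt(abs(cfg.latent_corr))
    resid = np.sqrt(1.0 - abs(cfg.latent_corr))
    ptau_std = load * latent + resid * rng_p.standard_normal(n)
    tau_std = load * latent + resid * rng_p.standard_normal(n)
    abeta_std = rng_p.standard_normal(n)

    def scaled(name: str, std_values: np.ndarray) -> np.ndarray:
        mu, sd = _ANALYTE_SCALES[name]
        return np.exp(mu + sd * std_values)

    tau_level = scaled("tau", tau_std)
    abeta_level = scaled("abeta42", abeta_std)
    pheno = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "ykl40": scaled("ykl40", y),
            "ptau181": scaled("ptau181", ptau_std),
            "tau": tau_level,
            "abeta42": abeta_level,
            "tau_abeta_ratio": tau_level / abeta_level,
            "age": age,
            "gender": gender.astype(int),
            "batch": batch.astype(int),
            "status": status,
        }
    )
    return geno, pheno


def validate_phenotypes(pheno: pd.DataFrame) -> None:
    """Check phenotype-table invariants; raise ValueError on violation."""
    if pheno["sample_id"].duplicated().any():
        raise ValueError("sample_id values must be unique")
    for col in ANALYTE_COLUMNS:
        if col in pheno:
            vals = pheno[col].dropna()
            if (vals <= 0).any():
                bad = pheno.loc[pheno[col] <= 0, "sample_id"].tolist()
                raise ValueError(f"analyte {col} must be strictly positive; offending samples: {bad}")
    if {"tau", "abeta42", "tau_abeta_ratio"} <= set(pheno.columns):
        both = pheno[["tau", "abeta42", "tau_abeta_ratio"]].dropna()
        if not np.allclose(both["tau_abeta_ratio"], both["tau"] / both["abeta42"], rtol=1e-9):
            raise ValueError("tau_abeta_ratio must equal tau/abeta42 where both present")
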