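"""Genotype quality control: call rate, MAF, Hardy-Weinberg, duplicates, PCA.

Variant and sample filters follow common GWAS practice for genotyped arrays:
samples are filtered on call rate first, then variants on call rate, minor
allele frequency and an exact Hardy-Weinberg test; duplicate individuals are
flagged by pairwise genotype concordance; population structure is summarized
by principal components of the standardized genotype matrix (EIGENSTRAT-style
(g - 2p)/sqrt(2p(1-p)) scaling with mean imputation of missing calls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = [
    "QCReport",
    "PrincipalComponents",
    "EmptyFilterError",
    "compute_maf",
    "hwe_exact_test",
    "filter_variants",
    "detect_duplicates",
    "pca_population_structure",
]


class EmptyFilterError(ValueError):
    """No variants or samples remain after filtering."""


@dataclass
class QCReport:
    variant_table: pd.DataFrame  # id, call_rate, maf, hwe_p, pass, reasons
    sample_table: pd.DataFrame  # sample_id, call_rate, pass
    thresholds: dict
    duplicate_pairs: list = field(default_factory=list)


@dataclass
class PrincipalComponents:
    sample_ids: list
    scores: np.ndarray  # n_samples x k, orthonormal columns
    eigenvalues: np.ndarray  # descending, nonnegative


def compute_maf(counts) -> float:
    """Minor allele frequency from an allele-count vector (NaN = missing)."""
    counts = np.asarray(counts, dtype=float)
    ok = ~np.isnan(counts)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("variant has no non-missing genotypes; MAF undefined")
    f = counts[ok].sum() / (2.0 * n)
    return float(min(f, 1.0 - f))


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Given the observed allele counts, sums the probabilities of all
    heterozygote counts whose conditional (hypergeometric-type) probability is
    no larger than that of the observed count.  Probabilities are built by a
    ratio recurrence outward from the modal heterozygote count, which keeps
    the arithmetic in a safe floating-point range for any table size.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValueError(f"genotype counts must be nonnegative integers, got {counts}")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")

    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_alt, 2 * n - n_alt)
    if rare == 0:
        return 1.0

    hs = np.arange(rare % 2, rare + 1, 2)
    # unnormalized probabilities via recurrence from the mode
    hom_rare = (rare - hs) / 2.0
    hom_common = (2 * n - rare - hs) / 2.0
    up = 4.0 * hom_rare[:-1] * hom_common[:-1] / ((hs[:-1] + 2.0) * (hs[:-1] + 1.0))
    mode_pos = int(np.argmin(np.abs(hs - rare * (2 * n - rare) / (2.0 * n - 1.0))))
    probs = np.empty(hs.size)
    probs[mode_pos] = 1.0
    if mode_pos + 1 < hs.size:
        probs[mode_pos + 1 :] = np.cumprod(up[mode_pos:])
    if mode_pos > 0:
        probs[:mode_pos] = np.cumprod(1.0 / up[:mode_pos][::-1])[::-1]
    probs /= probs.sum()

    obs = np.flatnonzero(hs == n_het)
    if obs.size == 0:  # observed het count infeasible for these allele counts
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = probs[obs[0]]
    p = float(probs[probs <= p_obs * (1.0 + 1e-10)].sum())
    return min(p, 1.0)


def _genotype_class_counts(col: np.ndarray) -> tuple[int, int, int]:
    ok = ~np.isnan(col)
    v = col[ok]
    return int((v == 0).sum()), int((v == 1).sum()), int((v == 2).sum())


def filter_variants(
    G: GenotypeMatrix,
    call_rate_min: float = 0.98,
    maf_min: float = 0.02,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample call-rate then variant call-rate/MAF/HWE filters.

    Samples are filtered first (call rate below ``call_rate_min`` excluded);
    variant statistics are then computed on the retained samples.  Every
    exclusion is recorded with its reason; retained variant order is
    preserved.  Raises :class:`EmptyFilterError` if nothing survives.
    """
    for name, v in (("call_rate_min", call_rate_min), ("maf_min", maf_min), ("hwe_alpha", hwe_alpha)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")

    missing = np.isnan(G.counts)
    sample_cr = 1.0 - missing.mean(axis=1)
    sample_pass = sample_cr >= call_rate_min
    sample_table = pd.DataFrame(
        {"sample_id": G.sample_ids, "call_rate": sample_cr, "pass": sample_pass,
         "reasons": np.where(sample_pass, "", "call_rate")}
    )
    if not sample_pass.any():
        raise EmptyFilterError("no samples pass the call-rate filter")
    Gs = G.subset_samples(sample_pass) if not sample_pass.all() else G

    m = Gs.n_variants
    call_rate = np.empty(m)
    maf = np.empty(m)
    hwe_p = np.empty(m)
    reasons: list[str] = []
    for j in range(m):
        col = Gs.counts[:, j]
        ok = ~np.isnan(col)
        call_rate[j] = ok.mean()
        r: list[str] = []
        if ok.any():
            maf[j] = compute_maf(col)
            hwe_p[j] = hwe_exact_test(*_genotype_class_counts(col))
        else:
            maf[j] = np.nan
            hwe_p[j] = np.nan
        if call_rate[j] < call_rate_min:
            r.append("call_rate")
        if not np.isnan(maf[j]) and maf[j] < maf_min:
            r.append("maf")
        if not np.isnan(hwe_p[j]) and hwe_p[j] < hwe_alpha:
            r.append("hwe")
        if not ok.any():
            r.append("all_missing")
        reasons.append(";".join(r))

    passed = np.array([r == "" for r in reasons])
    variant_table = pd.DataFrame(
        {
            "id": Gs.variants["id"].to_numpy(),
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "pass": passed,
            "reasons": reasons,
        }
    )
    if not passed.any():
        raise EmptyFilterError("no variants pass the QC filters")
    report = QCReport(
        variant_table=variant_table,
        sample_table=sample_table,
        thresholds={"call_rate_min": call_rate_min, "maf_min": maf_min, "hwe_alpha": hwe_alpha},
    )
    return Gs.subset_variants(passed), report


def detect_duplicates(G: GenotypeMatrix, sharing_min: float = 0.95) -> list[tuple[str, str, float]]:
    """Flag sample pairs with genotype concordance >= ``sharing_min``.

    Concordance is the fraction of variants, non-missing in both samples, at
    which the two genotype calls are identical.  Duplicates share ~1.0;
    unrelated individuals at common-variant MAF spectra share well below 0.95.
    """
    if not (0.0 < sharing_min <= 1.0):
        raise ValueError(f"sharing_min must be in (0, 1], got {sharing_min}")
    if G.n_samples < 2:
        warnings.warn("fewer than 2 samples; duplicate detection skipped")
        return []
    valid = (~np.isnan(G.counts)).astype(float)
    denom = valid @ valid.T
    numer = np.zeros_like(denom)
    for g in (0.0, 1.0, 2.0):
        ind = np.where(np.isnan(G.counts), 0.0, (G.counts == g).astype(float))
        numer += ind @ ind.T
    pairs = []
    iu, ju = np.triu_indices(G.n_samples, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sharing = numer[iu, ju] / denom[iu, ju]
    hit = np.flatnonzero((denom[iu, ju] > 0) & (sharing >= sharing_min))
    for k in hit:
        pairs.append((G.sample_ids[iu[k]], G.sample_ids[ju[k]], float(sharing[k])))
    return pairs


def pca_population_structure(G: GenotypeMatrix, k: int = 2) -> PrincipalComponents:
    """Top-k principal components of the standardized genotype matrix.

    Columns are standardized as (g - 2p)/sqrt(2p(1-p)) with p the observed
    alt-allele frequency; missing entries are mean-imputed (zero after
    centering).  Monomorphic variants are dropped.  Scores are the orthonormal
    sample eigenvectors of the genotypic covariance; eigenvalues descend.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if G.n_samples < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, have {G.n_samples}")
    counts = G.counts
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_hat = np.nanmean(counts, axis=0) / 2.0
    poly = np.isfinite(p_hat) & (p_hat > 0.0) & (p_hat < 1.0)
    if not poly.any():
        raise ValueError("all variants monomorphic; PCA undefined")
    X = counts[:, poly]
    p = p_hat[poly]
    X = (np.where(np.isnan(X), 2.0 * p, X) - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))

    u, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    scores = u[:, :k].copy()
    # deterministic sign: largest-magnitude loading of each PC made positive
    for j in range(k):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] *= -1.0
    eigenvalues = (s[:k] ** 2) / X.shape[1]
    return PrincipalComponents(list(G.sample_ids), scores, eigenvalues)
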