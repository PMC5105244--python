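"""Biomarker transformation, variance decomposition, genetic residualization.

The raw analyte is log-transformed and standardized; the variance explained by
covariates and the incremental variance explained by the top variant (delta
R-squared of nested linear models) are computed; and the genetically adjusted
biomarker is obtained as the studentized residuals of a regression of the
transformed level on the variant's allele counts.  Removing an orthogonal
genetic variance component rescales every correlation with an unrelated
analyte by 1/sqrt(1 - R2_G), which is how adjustment can strengthen a
biomarker-biomarker correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .association import fit_ols

__all__ = [
    "AdjustedPhenotype",
    "log_standardize",
    "normality_check",
    "variance_explained",
    "genetic_adjust",
]


@dataclass
class AdjustedPhenotype:
    sample_ids: list
    raw: np.ndarray
    log_standardized: np.ndarray
    adjusted: np.ndarray
    top_variant_id: str
    r2_covariates: float
    r2_variant: float


def log_standardize(values) -> np.ndarray:
    """Natural log, then z-score (n-1 denominator); NaN propagated."""
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if not ok.any():
        raise ValueError("no non-missing values")
    if (v[ok] <= 0).any():
        bad = np.flatnonzero(ok & (v <= 0)).tolist()
        raise ValueError(f"non-positive values at sample indices {bad}; log undefined")
    logs = np.where(ok, np.log(np.where(ok, v, 1.0)), np.nan)
    sd = np.nanstd(logs, ddof=1)
    if not np.isfinite(sd) or sd <= 1e-13 * max(1.0, abs(float(np.nanmean(logs)))):
        raise ValueError("constant (or single) input; standardization undefined")
    return (logs - np.nanmean(logs)) / sd


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p on non-missing values (advisory only)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if not (3 <= v.size <= 5000):
        raise ValueError(f"Shapiro-Wilk supported for 3 <= n <= 5000, got n={v.size}")
    w, p = stats.shapiro(v)
    return float(w), float(p)


def variance_explained(pheno, variant_counts, covariates) -> tuple[float, float]:
    """(R2 of covariate-only model, delta R2 from adding the variant).

    Both models are fit on the common complete-case set, so the variant's
    contribution is nonnegative by nesting.
    """
    y = np.asarray(pheno, dtype=float)
    g = np.asarray(variant_counts, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    ok = np.isfinite(y) & np.isfinite(g) & np.all(np.isfinite(C), axis=1)
    n = int(ok.sum())
    if n <= C.shape[1] + 2:
        raise ValueError("too few complete cases")
    ones = np.ones(n)
    fit0 = fit_ols(y[ok], np.column_stack([ones, C[ok]]))
    fit1 = fit_ols(y[ok], np.column_stack([ones, C[ok], g[ok]]))
    delta = fit1.r2 - fit0.r2
    if delta < -1e-9:
        raise AssertionError(f"nested-model delta R2 negative beyond tolerance: {delta}")
    return fit0.r2, max(delta, 0.0)


def genetic_adjust(
    pheno,
    variant_counts,
    sample_ids=None,
    variant_id: str = "",
    covariates=None,
    external: bool = True,
    with_covariates: bool = False,
    raw=None,
) -> AdjustedPhenotype:
    """Studentized residuals of pheno ~ intercept + allele counts.

    By default the adjustment regression contains only the intercept and the
    allele counts (covariate-augmented adjustment via ``with_covariates``),
    and residuals are externally studentized (leave-one-out variance;
    ``external=False`` selects internal studentization).  Samples missing the
    genotype keep a missing adjusted value.
    """
    y = np.asarray(pheno, dtype=float)
    g = np.asarray(variant_counts, dtype=float)
    if y.shape != g.shape:
        raise ValueError("phenotype and genotype vectors must align")
    C = None
    ok = np.isfinite(y) & np.isfinite(g)
    if with_covariates:
        if covariates is None:
            raise ValueError("with_covariates=True requires covariates")
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        ok &= np.all(np.isfinite(C), axis=1)
    n = int(ok.sum())
    if n < 10:
        raise ValueError(f"need at least 10 complete cases, have {n}")
    if np.std(g[ok]) == 0:
        raise ValueError("variant monomorphic among complete cases; nothing to adjust")

    if with_covariates:
        X = np.column_stack([np.ones(n), C[ok], g[ok]])
    else:
        X = np.column_stack([np.ones(n), g[ok]])
    fit = fit_ols(y[ok], X)
    e, h = fit.residuals, fit.leverage
    rss, df = float(e @ e), fit.df_resid
    if external:
        s2_loo = (rss - e**2 / (1.0 - h)) / (df - 1)
        stud = e / np.sqrt(s2_loo * (1.0 - h))
    else:
        stud = e / np.sqrt((rss / df) * (1.0 - h))

    adjusted = np.full(y.shape, np.nan)
    adjusted[ok] = stud
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(y.size)]
    if covariates is not None:
        r2_cov, r2_var = variance_explained(y, g, covariates)
    else:
        r2_cov, r2_var = 0.0, fit.r2
    return AdjustedPhenotype(
        sample_ids=list(sample_ids),
        raw=np.asarray(raw, dtype=float) if raw is not None else y.copy(),
        log_standardized=y.copy(),
        adjusted=adjusted,
        top_variant_id=variant_id,
        r2_covariates=r2_cov,
        r2_variant=r2_var,
    )
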