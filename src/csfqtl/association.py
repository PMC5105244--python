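"""Per-variant additive-model association, conditional analysis, inflation.

The quantitative trait (log-standardized biomarker) is regressed on each
variant's allele count plus covariates by ordinary least squares; two-sided
p-values come from the t distribution.  Missing genotypes are handled by
per-variant complete-case analysis.  A conditional scan appends an index
variant to the covariates.  Genomic inflation is the classic median-chi-square
diagnostic; significance classes follow the conventional genome-wide (5e-8)
and suggestive (1e-5) thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix

__all__ = [
    "OLSFit",
    "SingularDesignError",
    "GENOME_WIDE_P",
    "SUGGESTIVE_P",
    "fit_ols",
    "run_gwas",
    "conditional_analysis",
    "genomic_inflation",
    "classify_significance",
]

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-5

#: median of the central chi-square distribution with 1 df
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

ASSOC_COLUMNS = ["CHR", "POS", "ID", "A1", "A1_FREQ", "N", "BETA", "SE", "T", "P", "CLASS", "REASON"]


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank-deficient."""


@dataclass
class OLSFit:
    names: list
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    residuals: np.ndarray
    leverage: np.ndarray
    r2: float
    n: int
    df_resid: int


def fit_ols(y, X, names=None) -> OLSFit:
    """Ordinary least squares via QR, for a design that includes an intercept.

    Returns coefficients, classical standard errors sigma^2 (X'X)^-1,
    two-sided t-distribution p-values, residuals, hat-matrix diagonals and
    the (centered) coefficient of determination.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D and conformable with y")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if names is None:
        names = [f"x{j}" for j in range(p)]

    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= diag.max() * 1e-10:
        bad = [names[j] for j in np.flatnonzero(diag <= diag.max() * 1e-10)]
        raise SingularDesignError(f"singular design; collinear columns: {bad}")
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    leverage = np.einsum("ij,ij->i", Q, Q)
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    r_inv = np.linalg.solve(R, np.eye(p))
    se = np.sqrt(sigma2 * np.einsum("ij,ij->i", r_inv, r_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if tss == 0 else max(0.0, 1.0 - rss / tss)
    return OLSFit(list(names), beta, se, t, pvals, resid, leverage, r2, n, df)


def _prepare_covariates(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(
        covariates, dtype=float
    )
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows must match phenotype length")
    return C


def run_gwas(
    G: GenotypeMatrix,
    pheno,
    covariates=None,
    sort_by_p: bool = False,
) -> pd.DataFrame:
    """Additive-model scan: one OLS of pheno ~ intercept + covariates + G_j.

    Samples missing the phenotype or any covariate are excluded globally;
    samples missing a genotype are excluded for that variant only.  Variants
    monomorphic within their complete cases are emitted as NA rows with a
    reason code.  Effects are per copy of the counted (ALT) allele.
    """
    y = np.asarray(pheno, dtype=float)
    if y.shape[0] != G.n_samples:
        raise ValueError("phenotype length must match number of samples")
    C = _prepare_covariates(covariates, G.n_samples)
    base_ok = np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    if base_ok.sum() < C.shape[1] + 3:
        raise ValueError("too few complete cases for the covariate model")
    y0 = y[base_ok]
    X0 = np.column_stack([np.ones(base_ok.sum()), C[base_ok]])
    n0, p0 = X0.shape
    Q0, R0 = np.linalg.qr(X0)
    d0 = np.abs(np.diag(R0))
    if d0.min() <= d0.max() * 1e-10:
        raise SingularDesignError("collinear covariates in the GWAS design")
    y_res = y0 - Q0 @ (Q0.T @ y0)
    yty = float(y_res @ y_res)

    counts = G.counts[base_ok]
    m = G.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tstat = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    nvec = np.zeros(m, dtype=int)
    freq = np.full(m, np.nan)
    reason = np.array([""] * m, dtype=object)

    has_missing = np.isnan(counts).any(axis=0)
    full_idx = np.flatnonzero(~has_missing)
    if full_idx.size:
        Gf = counts[:, full_idx]
        nvec[full_idx] = n0
        freq[full_idx] = Gf.mean(axis=0) / 2.0
        mono = Gf.std(axis=0) == 0
        work = full_idx[~mono]
        reason[full_idx[mono]] = "monomorphic"
        if work.size:
            Gw = counts[:, work]
            Gres = Gw - Q0 @ (Q0.T @ Gw)
            gtg = np.einsum("ij,ij->j", Gres, Gres)
            gvar = np.einsum("ij,ij->j", Gw - Gw.mean(0), Gw - Gw.mean(0))
            collinear = gtg <= gvar * 1e-10
            reason[work[collinear]] = "collinear_with_covariates"
            work = work[~collinear]
            Gres, gtg = Gres[:, ~collinear], gtg[~collinear]
            gty = Gres.T @ y_res
            df = n0 - p0 - 1
            b = gty / gtg
            rss = yty - b * gty
            s = np.sqrt(np.maximum(rss, 0.0) / df / gtg)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = b / s
            beta[work] = b
            se[work] = s
            tstat[work] = t
            pval[work] = np.maximum(2.0 * stats.t.sf(np.abs(t), df), 5e-324)

    for j in np.flatnonzero(has_missing):
        g = counts[:, j]
        ok = ~np.isnan(g)
        nvec[j] = int(ok.sum())
        if nvec[j] == 0:
            reason[j] = "all_missing"
            continue
        freq[j] = g[ok].mean() / 2.0
        if g[ok].std() == 0:
            reason[j] = "monomorphic"
            continue
        if nvec[j] <= p0 + 1:
            reason[j] = "insufficient_n"
            continue
        try:
            fit = fit_ols(y0[ok], np.column_stack([X0[ok], g[ok]]))
        except SingularDesignError:
            reason[j] = "collinear_with_covariates"
            continue
        beta[j], se[j], tstat[j] = fit.beta[-1], fit.se[-1], fit.t[-1]
        pval[j] = max(fit.p[-1], 5e-324)

    cls = np.array(
        [classify_significance(p) if np.isfinite(p) else "NA" for p in pval], dtype=object
    )
    out = pd.DataFrame(
        {
            "CHR": G.variants["chrom"].to_numpy(),
            "POS": G.variants["pos"].to_numpy(),
            "ID": G.variants["id"].to_numpy(),
            "A1": G.variants["counted_allele"].to_numpy(),
            "A1_FREQ": freq,
            "N": nvec,
            "BETA": beta,
            "SE": se,
            "T": tstat,
            "P": pval,
            "CLASS": cls,
            "REASON": reason,
        }
    )
    if sort_by_p:
        out = out.sort_values(["P", "CHR", "POS"], kind="mergesort").reset_index(drop=True)
    return out


def conditional_analysis(
    G: GenotypeMatrix,
    pheno,
    covariates,
    index_variant_id: str,
) -> pd.DataFrame:
    """Re-run the scan with the index variant's allele counts as a covariate.

    Samples missing the index genotype are dropped; the index variant's own
    row is reported NA with reason ``conditioned_on``.
    """
    idx = G.variant_index(index_variant_id)
    g_idx = G.counts[:, idx]
    ok = ~np.isnan(g_idx)
    C = _prepare_covariates(covariates, G.n_samples)
    C_cond = np.column_stack([C[ok], g_idx[ok]])
    Gsub = G.subset_samples(ok) if not ok.all() else G
    y = np.asarray(pheno, dtype=float)[ok]
    out = run_gwas(Gsub, y, C_cond)
    na_cols = ["A1_FREQ", "BETA", "SE", "T", "P"]
    out.loc[idx, na_cols] = np.nan
    out.loc[idx, ["CLASS", "REASON"]] = ["NA", "conditioned_on"]
    return out


def genomic_inflation(p_values) -> float:
    """lambda = median observed chi-square (1 df) / 0.4549364."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / _CHI2_1_MEDIAN)


def classify_significance(p: float) -> str:
    """'genome-wide' below 5e-8, 'suggestive' below 1e-5, else 'ns'."""
    if not np.isfinite(p) or not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    if p < GENOME_WIDE_P:
        return "genome-wide"
    if p < SUGGESTIVE_P:
        return "suggestive"
    return "ns"
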