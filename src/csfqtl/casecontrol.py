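"""Logistic-regression association of the biomarker with case/control status.

Maximum likelihood is obtained by iteratively reweighted least squares with
step-halving (so the deviance decreases monotonically); Wald tests give
per-coefficient z statistics and two-sided p-values.  Complete or
quasi-complete separation is surfaced as an error rather than silently
returning diverged estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .adjust import log_standardize

__all__ = [
    "LogisticFit",
    "SeparationError",
    "fit_logistic",
    "test_status_association",
]


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation; ML estimate does not exist."""


@dataclass
class LogisticFit:
    names: list
    beta: np.ndarray  # log-odds scale
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n: int
    converged: bool
    iterations: int
    deviance: float


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-300, 1 - 1e-16)
    return float(-2.0 * (y @ np.log(mu) + (1 - y) @ np.log1p(-mu)))


def fit_logistic(y, X, names=None, tol: float = 1e-8, max_iter: int = 50) -> LogisticFit:
    """Binomial GLM with logit link, fit by IRLS.

    Convergence: max absolute coefficient change below ``tol``.  Diverging
    linear predictors (|X beta| beyond ~30 while the deviance keeps falling)
    indicate separation and raise :class:`SeparationError`.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D and conformable with y")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if names is None:
        names = [f"x{j}" for j in range(p)]

    beta = np.zeros(p)
    eta = X @ beta
    dev = _deviance(y, expit(eta))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        if w.max() < 1e-12:
            raise SeparationError("all fitted probabilities degenerate")
        z_work = eta + (y - mu) / np.maximum(w, 1e-12)
        sw = np.sqrt(w)
        Q, R = np.linalg.qr(X * sw[:, None])
        diag = np.abs(np.diag(R))
        if diag.min() <= diag.max() * 1e-12:
            raise np.linalg.LinAlgError("singular weighted design in IRLS")
        beta_new = np.linalg.solve(R, Q.T @ (z_work * sw))

        # step-halving keeps the deviance monotone
        step = beta_new - beta
        for _ in range(30):
            cand = beta + step
            dev_new = _deviance(y, expit(X @ cand))
            if dev_new <= dev + 1e-12:
                break
            step /= 2.0
        beta_new = beta + step
        eta = X @ beta_new
        if np.abs(eta).max() > 30.0:
            raise SeparationError(
                "diverging coefficients (|linear predictor| > 30): "
                "data are completely or quasi-completely separated"
            )
        delta = np.abs(beta_new - beta).max()
        beta, dev = beta_new, dev_new
        if delta < tol:
            converged = True
            break

    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    XtWX = (X * w[:, None]).T @ X
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 5e-324)
    return LogisticFit(list(names), beta, se, z, pvals, n, converged, it, dev)


def _batch_indicators(batch: np.ndarray) -> tuple[np.ndarray, list[str]]:
    levels = np.unique(batch)
    cols = [(batch == lv).astype(float) for lv in levels[1:]]  # first level = reference
    names = [f"batch_{int(lv)}" for lv in levels[1:]]
    return (np.column_stack(cols) if cols else np.empty((batch.size, 0))), names


def test_status_association(
    pheno: pd.DataFrame,
    analyte_col: str = "ykl40",
    covariate_cols=("age", "gender", "batch"),
    log_std: bool = True,
) -> LogisticFit:
    """Logistic fit of case/control status on the analyte plus covariates.

    The analyte enters log-standardized by default (``log_std=False`` uses the
    raw/precomputed column, e.g. an already-adjusted biomarker); batch is
    expanded to indicator columns with the first batch as reference.  The
    analyte coefficient is the first non-intercept entry of the fit.
    """
    if "status" not in pheno:
        raise ValueError("phenotype table has no status column")
    analyte = pheno[analyte_col].to_numpy(dtype=float)
    x_analyte = log_standardize(analyte) if log_std else analyte

    cov_arrays, names = [x_analyte], ["intercept", analyte_col]
    for c in covariate_cols:
        v = pheno[c].to_numpy(dtype=float)
        if c == "batch":
            ind, bn = _batch_indicators(v)
            for k in range(ind.shape[1]):
                cov_arrays.append(ind[:, k])
            names.extend(bn)
        else:
            cov_arrays.append(v)
            names.append(c)
    M = np.column_stack(cov_arrays)
    y = pheno["status"].to_numpy(dtype=float)
    ok = np.all(np.isfinite(M), axis=1) & np.isfinite(y)
    X = np.column_stack([np.ones(int(ok.sum())), M[ok]])
    return fit_logistic(y[ok], X, names=names)


# the name starts with "test_" for API reasons; it is not a pytest test
test_status_association.__test__ = False
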