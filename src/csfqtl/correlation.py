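"""Pearson correlations and the Meng Z-test for dependent correlations.

When the same cohort provides the biomarker, its genetically adjusted version
and a target analyte, the two target correlations r_jk (target vs unadjusted)
and r_jh (target vs adjusted) are dependent and overlapping: they share the
target variable j.  Meng, Rosenthal & Rubin's Z-test compares them via Fisher
z-transforms with a variance correction driven by r_kh, the correlation
between the two biomarker versions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationComparison", "pearson", "fisher_z", "meng_test", "compare_adjusted"]

_Z975 = 1.959964  # two-sided 95% normal quantile


@dataclass
class CorrelationComparison:
    r_jk: float  # target vs unadjusted biomarker
    r_jh: float  # target vs adjusted biomarker
    r_kh: float  # unadjusted vs adjusted
    n: int
    z_jk: float
    z_jh: float
    Z: float
    p: float
    ci_low: float
    ci_high: float
    decision: str  # "retain" iff the 95% CI (Fisher-z difference scale) includes 0


def pearson(x, y) -> tuple[float, float, int]:
    """Complete-pairs Pearson r with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, have {n}")
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("constant vector; undefined correlation")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n


def fisher_z(r: float) -> float:
    """Fisher variance-stabilizing transform z = arctanh(r)."""
    if not np.isfinite(r) or abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1 for the Fisher transform, got {r}")
    return float(np.arctanh(r))


def meng_test(r_jk: float, r_jh: float, r_kh: float, n: int) -> CorrelationComparison:
    """Compare two dependent overlapping correlations (shared variable j).

    Z = (z_jk - z_jh) * sqrt((n-3) / (2(1-r_kh) h)) with
    rbar2 = (r_jk^2 + r_jh^2)/2, f = min(1, (1-r_kh)/(2(1-rbar2))) and
    h = (1 - f*rbar2)/(1 - rbar2).  The 95% CI is reported on the Fisher-z
    difference scale, and the null is retained iff it includes 0.
    """
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh)):
        if not np.isfinite(r) or abs(r) >= 1.0:
            raise ValueError(f"|{name}| must be < 1, got {r}")
    if not np.isfinite(r_kh) or abs(r_kh) > 1.0:
        raise ValueError(f"r_kh must be in [-1, 1], got {r_kh}")
    corr = np.array([[1.0, r_jk, r_jh], [r_jk, 1.0, r_kh], [r_jh, r_kh, 1.0]])
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("impossible correlation structure (matrix not positive semidefinite)")

    z_jk, z_jh = fisher_z(r_jk), fisher_z(r_jh)
    diff = z_jk - z_jh
    if r_kh >= 1.0 - 1e-15:
        # degenerate: the two biomarker versions coincide, so the correlations
        # are identical and the comparison carries no information
        return CorrelationComparison(r_jk, r_jh, r_kh, n, z_jk, z_jh, 0.0, 1.0, 0.0, 0.0, "retain")

    rbar2 = (r_jk**2 + r_jh**2) / 2.0
    f = min(1.0, (1.0 - r_kh) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    se = np.sqrt(2.0 * (1.0 - r_kh) * h / (n - 3))
    Z = diff / se
    p = max(2.0 * stats.norm.sf(abs(Z)), 5e-324)
    ci_low, ci_high = diff - _Z975 * se, diff + _Z975 * se
    decision = "retain" if ci_low <= 0.0 <= ci_high else "reject"
    return CorrelationComparison(
        float(r_jk), float(r_jh), float(r_kh), int(n),
        z_jk, z_jh, float(Z), float(p), float(ci_low), float(ci_high), decision,
    )


def compare_adjusted(
    pheno: pd.DataFrame,
    biomarker_col: str,
    adjusted_col: str,
    target_col: str,
) -> CorrelationComparison:
    """Meng comparison of target correlations before vs after adjustment.

    All three correlations are computed on the single common complete-case
    set, as the Meng formula assumes one n.
    """
    cols = [target_col, biomarker_col, adjusted_col]
    block = pheno[cols].to_numpy(dtype=float)
    ok = np.all(np.isfinite(block), axis=1)
    n = int(ok.sum())
    if n < 4:
        raise ValueError(f"need at least 4 complete samples across {cols}, have {n}")
    sub = block[ok]
    if np.any(sub.std(axis=0) == 0):
        raise ValueError("constant column; undefined correlation")
    R = np.corrcoef(sub, rowvar=False)
    return meng_test(r_jk=R[0, 1], r_jh=R[0, 2], r_kh=R[1, 2], n=n)
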