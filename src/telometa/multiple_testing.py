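"""Multiple-testing correction for correlated metabolites.

With m correlated tests a plain Bonferroni factor m is conservative.  The
effective number of independent tests is estimated from the eigenvalues
``lambda_1 >= ... >= lambda_m`` of the metabolite correlation matrix as

    Veff = sum_i [ 1{lambda_i >= 1} + (lambda_i - floor(lambda_i)) ]

i.e. each eigenvalue contributes its integer part capped at one plus its
fractional part.  Veff equals m for the identity matrix and 1 when all
variables are perfectly correlated.  The family-wise threshold is
``alpha / ceil(Veff)`` (the integer form matches the convention of the matSpD
tool).  Benjamini-Hochberg step-up FDR values are provided for per-row
reporting, with an optional total-test-count override so a subset of p-values
can be adjusted against the full panel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VeffReport",
    "veff_li",
    "bonferroni_threshold",
    "bh_adjust",
    "significance_stars",
    "flag_significant",
]

#: eigenvalues more negative than this (from pairwise-complete, possibly
#: non-PSD correlation estimates) are an error rather than numerical noise
NEGATIVE_EIGVALUE_TOL = -1e-6


@dataclass
class VeffReport:
    m: int
    eigenvalues: np.ndarray  # sorted descending
    veff_raw: float
    veff_int: int
    alpha: float
    threshold: float


def veff_li(corr: pd.DataFrame | np.ndarray, alpha: float = 0.05) -> VeffReport:
    """Effective number of independent tests from a correlation matrix.

    The matrix must be square, symmetric (to 1e-8) with unit diagonal.  Tiny
    negative eigenvalues (> -1e-6) arising from pairwise-complete estimation
    are absolute-valued; anything more negative raises.
    """
    R = np.asarray(corr, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric (tolerance 1e-8)")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    m = R.shape[0]
    lam = np.linalg.eigvalsh((R + R.T) / 2.0)
    if lam.min() < NEGATIVE_EIGVALUE_TOL:
        raise ValueError(f"correlation matrix far from PSD (min eigenvalue {lam.min():.3g})")
    lam = np.abs(lam)[::-1]  # descending
    # f has a jump at every integer; snap eigenvalues that are integers up to
    # rounding error so e.g. an exact 3 computed as 3 - 4e-15 contributes 1,
    # not ~2
    near_int = np.abs(lam - np.round(lam)) < 1e-8 * max(1.0, m)
    lam = np.where(near_int, np.round(lam), lam)
    f = (lam >= 1.0).astype(float) + (lam - np.floor(lam))
    veff_raw = float(f.sum())
    veff_int = int(math.ceil(veff_raw - 1e-9))
    return VeffReport(
        m=m,
        eigenvalues=lam,
        veff_raw=veff_raw,
        veff_int=veff_int,
        alpha=alpha,
        threshold=bonferroni_threshold(alpha, veff_int),
    )


def bonferroni_threshold(alpha: float, veff_int: int) -> float:
    """Family-wise significance threshold alpha / veff."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if veff_int < 1:
        raise ValueError("veff_int must be >= 1")
    return alpha / veff_int


def bh_adjust(pvals, m_override: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``m_override`` adjusts against a larger total test count than the list
    supplied (the omitted tests are treated as p = 1, which cannot lower any
    head value): ``q_i = p_(i) * m / rank_i`` with the usual monotone
    enforcement and cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p) if m_override is None else int(m_override)
    if m < len(p):
        raise ValueError("m_override must be >= len(pvals)")
    padded = np.concatenate([p, np.ones(m - len(p))])
    adjusted = multipletests(padded, method="fdr_bh")[1]
    return adjusted[: len(p)]


def significance_stars(p: float) -> str:
    """Plot star codes: '***' p<0.001, '**' p<0.01, '*' p<0.05, else ''."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def flag_significant(meta_results: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Annotate pooled results with the strict ``p < threshold`` flag and stars."""
    out = meta_results.copy()
    out["significant"] = out["p"] < threshold
    out["stars"] = out["p"].map(significance_stars)
    return out
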