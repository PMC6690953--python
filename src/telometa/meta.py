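"""Fixed-effect meta-analysis of per-cohort partial correlations.

Cohort correlations are pooled on Fisher's z scale,
``z = atanh(r) = 0.5 ln((1+r)/(1-r))``, with inverse-variance weights
``w_i = n_i - k_i - 3`` (the reciprocal of the asymptotic variance of z for a
partial correlation adjusting k covariates).  The pooled estimate is
``zbar = sum(w z) / sum(w)`` with standard error ``1/sqrt(sum(w))``; the
two-sided p-value comes from the normal reference, and the pooled r is
``tanh(zbar)``.  A sample-size-weighted variant (``w_i = n_i``) is available
for comparison.  Cochran's Q and I^2 are reported as heterogeneity
diagnostics but play no role in model selection.

Each pooled row also carries a direction string: one character per cohort in
a fixed configured order — '+' / '−'(minus) by the sign of the cohort r, '0'
when the cohort r rounds to 0.00 at reporting precision, and '?' when the
cohort contributed no estimate (metabolite failed QC there).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fisher_z",
    "inv_fisher",
    "meta_fixed",
    "direction_string",
    "meta_all",
    "sensitivity_excluding",
]

#: |r| below which the direction character is '0' (rounds to 0.00 at the
#: 2-decimal reporting precision).
ZERO_DIRECTION_TOL = 0.005


def fisher_z(r) -> float | np.ndarray:
    """Variance-stabilizing transform z = 0.5 ln((1+r)/(1-r)); |r| must be < 1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def inv_fisher(z) -> float | np.ndarray:
    """Inverse transform r = tanh(z)."""
    arr = np.asarray(z, dtype=float)
    out = np.tanh(arr)
    return float(out) if np.isscalar(z) or arr.ndim == 0 else out


def meta_fixed(results: pd.DataFrame, weights: str = "inverse_variance") -> dict:
    """Pool one metabolite's per-cohort results (columns r, n, k).

    Returns a dict with r_meta, z, se, p, n_total, n_cohorts, Q, I2.
    ``weights``: ``"inverse_variance"`` (w = n - k - 3, default) or
    ``"sample_size"`` (w = n).
    """
    if len(results) == 0:
        raise ValueError("meta_fixed requires at least one cohort result")
    r = results["r"].to_numpy(dtype=float)
    n = results["n"].to_numpy(dtype=float)
    k = results["k"].to_numpy(dtype=float)
    if weights == "inverse_variance":
        w = n - k - 3.0
    elif weights == "sample_size":
        w = n.copy()
    else:
        raise ValueError(f"unknown weighting scheme {weights!r}")
    if np.any(w <= 0):
        raise ValueError("non-positive meta-analysis weight (cohort too small)")
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    zbar = float(np.sum(w * z) / np.sum(w))
    se = 1.0 / math.sqrt(float(np.sum(w)))
    stat = zbar / se
    p = max(2.0 * stats.norm.sf(abs(stat)), np.finfo(float).tiny)
    q = float(np.sum(w * (z - zbar) ** 2))
    dof = len(r) - 1
    i2 = max(0.0, (q - dof) / q) if (dof > 0 and q > 0) else 0.0
    return {
        "r_meta": math.tanh(zbar),
        "z": zbar,
        "se": se,
        "p": float(p),
        "n_total": int(n.sum()),
        "n_cohorts": int(len(r)),
        "Q": q,
        "I2": i2,
    }


def direction_string(per_cohort_r: Mapping[str, float], cohort_order: Sequence[str]) -> str:
    """Per-cohort sign summary over the configured cohort order."""
    chars = []
    for cohort in cohort_order:
        if cohort not in per_cohort_r or per_cohort_r[cohort] is None or np.isnan(per_cohort_r[cohort]):
            chars.append("?")
        else:
            r = float(per_cohort_r[cohort])
            if abs(r) < ZERO_DIRECTION_TOL:
                chars.append("0")
            elif r > 0:
                chars.append("+")
            else:
                chars.append("-")
    return "".join(chars)


def meta_all(
    per_cohort: pd.DataFrame,
    cohort_order: Sequence[str],
    weights: str = "inverse_variance",
) -> pd.DataFrame:
    """Pool every metabolite in a tidy per-cohort results frame.

    ``per_cohort`` needs columns cohort, metabolite, model, n, k, r (p
    optional).  Returns one row per metabolite with the pooled statistics and
    the direction string, sorted by pooled p then metabolite name.
    """
    if len(per_cohort) == 0:
        raise ValueError("no per-cohort results to pool")
    models = per_cohort["model"].unique()
    if len(models) != 1:
        raise ValueError(f"meta_all expects a single model, got {list(models)}")
    rows = []
    for met, grp in per_cohort.groupby("metabolite", sort=True):
        pooled = meta_fixed(grp, weights=weights)
        signs = dict(zip(grp["cohort"], grp["r"]))
        rows.append(
            {
                "metabolite": met,
                "model": models[0],
                "n": pooled["n_total"],
                "n_cohorts": pooled["n_cohorts"],
                "direction": direction_string(signs, cohort_order),
                "r": pooled["r_meta"],
                "p": pooled["p"],
                "se_z": pooled["se"],
                "Q": pooled["Q"],
                "I2": pooled["I2"],
                "cohorts_included": ";".join(grp["cohort"]),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["p", "metabolite"], kind="mergesort").reset_index(drop=True)


def sensitivity_excluding(
    per_cohort: pd.DataFrame,
    exclude: Sequence[str],
    cohort_order: Sequence[str],
    threshold: float | None = None,
    weights: str = "inverse_variance",
) -> pd.DataFrame:
    """Re-pool after dropping the named cohorts (leave-cohort-out analysis).

    With ``threshold`` given, flags metabolites whose significance verdict
    changes relative to the full meta-analysis (column ``crossed``:
    'lost', 'gained' or '').
    """
    exclude = set(exclude)
    remaining = per_cohort[~per_cohort["cohort"].isin(exclude)]
    if len(remaining) == 0:
        raise ValueError("sensitivity analysis would exclude every cohort")
    sub = meta_all(remaining, cohort_order, weights=weights)
    if threshold is not None:
        full = meta_all(per_cohort, cohort_order, weights=weights).set_index("metabolite")
        before = full["p"] < threshold
        after = sub.set_index("metabolite")["p"] < threshold
        crossed = []
        for met in sub["metabolite"]:
            b = bool(before.get(met, False))
            a = bool(after.get(met, False))
            crossed.append("lost" if b and not a else "gained" if a and not b else "")
        sub = sub.assign(crossed=crossed)
    return sub
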