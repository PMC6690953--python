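"""Cohort descriptive statistics with normal-approximation confidence bounds."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CohortTable

__all__ = ["normal_approx_ci", "cohort_summary", "table_one"]

_Z975 = stats.norm.ppf(0.975)


def normal_approx_ci(mean: float, sd: float, n: int) -> tuple[float, float]:
    """95% CI for a mean: mean +/- z_0.975 * sd / sqrt(n)."""
    if n < 1 or sd < 0:
        raise ValueError("need n >= 1 and sd >= 0")
    half = _Z975 * sd / math.sqrt(n)
    return mean - half, mean + half


def cohort_summary(table: CohortTable) -> dict:
    """Demographic summary of one cohort (mean, SD and 95% CI per trait)."""
    out: dict = {"cohort": table.name, "n": table.n,
                 "pct_female": 100.0 * float((table.data["sex"] == "F").mean())}
    for trait in ("ltl", "age", "bmi"):
        if trait not in table.data.columns:
            continue
        v = table.data[trait].dropna()
        if len(v) == 0:
            continue
        mean, sd = float(v.mean()), float(v.std(ddof=1))
        lo, hi = normal_approx_ci(mean, sd, len(v))
        out[f"{trait}_n"] = len(v)
        out[f"{trait}_mean"] = mean
        out[f"{trait}_sd"] = sd
        out[f"{trait}_ci_low"] = lo
        out[f"{trait}_ci_high"] = hi
    return out


def table_one(cohorts: list[CohortTable]) -> pd.DataFrame:
    """Stacked demographic summary, one row per cohort."""
    return pd.DataFrame([cohort_summary(t) for t in cohorts])
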