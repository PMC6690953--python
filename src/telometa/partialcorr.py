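"""Covariate-adjusted partial correlation of LTL with each metabolite.

The partial correlation between LTL (Z-scored) and a log-concentration given
covariates is the Pearson correlation of the two least-squares residual
vectors after projecting each variable onto the covariates (with intercept).
Significance uses the t statistic ``t = r * sqrt(df / (1 - r^2))`` with
``df = n - 2 - k`` (k adjusting covariates, which consume degrees of
freedom), two-sided.

Family-structured cohorts (twins, sibships) violate the independence the t
test assumes.  Three adjustment modes are provided:

``mixed_residual`` (default)
    Residualize each variable on the covariates with an additional per-family
    Gaussian random intercept (one-way REML, profiled over the
    between/within variance ratio), subtracting both the fixed-effect fit and
    the BLUP family intercepts before correlating.
``one_per_family``
    Seeded random selection of one member per family, then the plain partial
    correlation on the reduced sample.
``none``
    Ignore relatedness.

Rows enter a given correlation only if LTL, the metabolite and every model
covariate are present (available-case analysis), so n varies by metabolite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .qc import AnalysisMatrix

__all__ = [
    "ModelSpec",
    "MODEL1",
    "MODEL2",
    "CorrelationResult",
    "residualize",
    "partial_corr",
    "partial_corr_family",
    "analyze_cohort",
    "reml_random_intercept",
]

FAMILY_MODES = ("none", "mixed_residual", "one_per_family")


@dataclass(frozen=True)
class ModelSpec:
    """An adjustment model: ordered covariates plus the family mode."""

    id: str
    covariates: tuple[str, ...]
    family_adjustment: str = "mixed_residual"

    def __post_init__(self):
        if self.family_adjustment not in FAMILY_MODES:
            raise ValueError(f"unknown family_adjustment {self.family_adjustment!r}")


MODEL1 = ModelSpec("model1", ("age", "sex"))
MODEL2 = ModelSpec("model2", ("age", "sex", "bmi"))

MODELS = {"model1": MODEL1, "model2": MODEL2}


@dataclass
class CorrelationResult:
    cohort: str
    metabolite: str
    model: str
    r: float
    n_used: int
    k: int
    df: int
    p: float


# ---------------------------------------------------------------------------
# core estimators
# ---------------------------------------------------------------------------


def _prune_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop columns that are (numerically) linear combinations of earlier ones."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=1e-8 * max(1.0, np.abs(cand).max())) == len(keep) + 1:
            keep.append(j)
    if not keep:
        raise ValueError(f"design matrix has no independent columns (dropped all of {names})")
    return X[:, keep], [names[j] for j in keep]


def residualize(y, X, names: list[str] | None = None) -> np.ndarray:
    """Residual of ``y`` after least-squares projection onto span(X).

    ``X`` must include the intercept column if one is wanted.  Exactly
    collinear columns are pruned before fitting; the residuals are orthogonal
    to every retained column.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("rows(X) must equal len(y)")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    Xp, _ = _prune_collinear(X, list(names))
    beta, *_ = np.linalg.lstsq(Xp, y, rcond=None)
    return y - Xp @ beta


def _design(df: pd.DataFrame, covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str], int]:
    """Intercept + covariates; returns (matrix, names, k after pruning)."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for c in covariates:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    Xp, kept = _prune_collinear(X, names)
    k = len([n for n in kept if n != "intercept"])
    return Xp, kept, k


def _corr_with_p(rx: np.ndarray, ry: np.ndarray, k: int) -> tuple[float, int, float]:
    n = rx.size
    df = n - 2 - k
    if df < 1:
        raise ValueError(f"insufficient degrees of freedom (n={n}, k={k})")
    sx = rx.std(ddof=0)
    sy = ry.std(ddof=0)
    if sx <= 0 or sy <= 0:
        raise ValueError("zero-variance residuals")
    r = float(np.clip(np.dot(rx - rx.mean(), ry - ry.mean()) / (n * sx * sy), -1.0, 1.0))
    if abs(r) >= 1.0:
        p = np.finfo(float).tiny
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
        p = max(float(p), np.finfo(float).tiny)
    return r, df, p


def partial_corr(x, y, X, k: int | None = None) -> tuple[float, int, float]:
    """Partial correlation of x and y given the columns of X (with intercept).

    Returns ``(r, df, p)`` with ``df = n - 2 - k``.  ``k`` defaults to the
    number of non-constant covariate columns in ``X``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k is None:
        k = sum(1 for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0)
    if x.shape[0] < k + 4:
        raise ValueError(f"insufficient rows: n={x.shape[0]} < k+4={k + 4}")
    rx = residualize(x, X)
    ry = residualize(y, X)
    r, df, p = _corr_with_p(rx, ry, k)
    return r, df, p


# ---------------------------------------------------------------------------
# one-way random-intercept REML
# ---------------------------------------------------------------------------


def reml_random_intercept(y, X, groups) -> tuple[np.ndarray, float, np.ndarray]:
    """Fit ``y = X b + u_group + e`` by REML; return conditional residuals.

    Profiles the restricted likelihood over the variance ratio
    ``lambda = var(u) / var(e)`` using per-group sufficient statistics, then
    subtracts both the GLS fixed-effect fit and the BLUP group intercepts.
    Returns ``(conditional residuals, lambda_hat, beta_hat)``.  Singleton-only
    grouping degenerates gracefully (residuals proportional to OLS residuals).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = codes.max() + 1
    sizes = np.bincount(codes).astype(float)

    # per-group sums of X columns and of y
    SX = np.zeros((n_groups, p))
    np.add.at(SX, codes, X)
    Sy = np.bincount(codes, weights=y)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def fit(lam: float):
        a = lam / (1.0 + lam * sizes)  # per-group shrink coefficient
        XtWX = XtX - (SX * a[:, None]).T @ SX
        XtWy = Xty - SX.T @ (a * Sy)
        beta = np.linalg.solve(XtWX, XtWy)
        resid = y - X @ beta
        Sr = np.bincount(codes, weights=resid, minlength=n_groups)
        quad = float(resid @ resid - np.sum(a * Sr * Sr))
        return beta, resid, Sr, quad, XtWX

    def neg2_reml(log_lam: float) -> float:
        lam = math.exp(log_lam)
        _, _, _, quad, XtWX = fit(lam)
        sign, logdet = np.linalg.slogdet(XtWX)
        return (n - p) * math.log(max(quad, 1e-300)) + float(
            np.sum(np.log1p(lam * sizes))
        ) + logdet

    if np.all(sizes <= 1):
        lam_hat = 0.0
    else:
        res = optimize.minimize_scalar(neg2_reml, bounds=(-12.0, 8.0), method="bounded",
                                       options={"xatol": 1e-6})
        lam_hat = math.exp(res.x)
        if neg2_reml(-30.0) <= res.fun:  # boundary: no between-family variance
            lam_hat = 0.0

    beta, resid, Sr, _, _ = fit(lam_hat)
    shrink = lam_hat * sizes / (1.0 + lam_hat * sizes)
    u_hat = shrink * (Sr / sizes)
    return resid - u_hat[codes], lam_hat, beta


def partial_corr_family(
    x, y, X, family_id, mode: str = "mixed_residual", seed: int | None = None,
    k: int | None = None,
) -> tuple[float, int, int, float]:
    """Partial correlation with family-relatedness adjustment.

    Returns ``(r, n_used, df, p)``.  See module docstring for the modes.
    ``one_per_family`` selects the member via a seeded RNG over members in
    input (sample_id-sorted) order, so the subset is reproducible.
    """
    if mode not in FAMILY_MODES:
        raise ValueError(f"unknown family mode {mode!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k is None:
        k = sum(1 for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0)

    if mode == "none":
        r, df, p = partial_corr(x, y, X, k=k)
        return r, x.shape[0], df, p

    if mode == "one_per_family":
        rng = np.random.default_rng(seed)
        codes, _ = pd.factorize(np.asarray(family_id))
        pick = np.full(codes.max() + 1, -1, dtype=int)
        counts = np.bincount(codes)
        draws = rng.random(len(counts))
        seen = np.zeros(len(counts), dtype=int)
        for i, c in enumerate(codes):
            # reservoir-free deterministic pick: index floor(draw * size)
            if seen[c] == int(draws[c] * counts[c]):
                pick[c] = i
            seen[c] += 1
        idx = np.sort(pick)
        r, df, p = partial_corr(x[idx], y[idx], X[idx], k=k)
        return r, idx.size, df, p

    # mixed_residual
    if x.shape[0] < k + 4:
        raise ValueError(f"insufficient rows: n={x.shape[0]} < k+4={k + 4}")
    Xp, _ = _prune_collinear(X, [f"x{j}" for j in range(X.shape[1])])
    rx, _, _ = reml_random_intercept(x, Xp, family_id)
    ry, _, _ = reml_random_intercept(y, Xp, family_id)
    r, df, p = _corr_with_p(rx, ry, k)
    return r, x.shape[0], df, p


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------


def analyze_cohort(
    am: AnalysisMatrix,
    model: ModelSpec | str = MODEL1,
    family_mode: str | None = None,
    seed: int | None = None,
    min_n: int = 10,
) -> pd.DataFrame:
    """Partial correlation of LTL with every kept metabolite in one cohort.

    Available-case rows are selected per metabolite.  Metabolites with fewer
    than ``min_n`` usable rows are skipped.  Returns a tidy frame with
    columns cohort, metabolite, model, n, k, df, r, p.
    """
    if isinstance(model, str):
        model = MODELS[model]
    mode = family_mode if family_mode is not None else model.family_adjustment
    for cov in model.covariates:
        if cov not in am.data.columns:
            raise ValueError(f"cohort {am.cohort!r} lacks covariate {cov!r} for {model.id}")
    rows = []
    base = am.data
    for met in am.metabolites:
        cols = ["ltl_z", met, *model.covariates]
        sub = base[cols + ["family_id"]].dropna(subset=cols)
        if len(sub) < max(min_n, len(model.covariates) + 4):
            continue
        X, _, k = _design(sub, model.covariates)
        r, n_used, df, p = partial_corr_family(
            sub["ltl_z"].to_numpy(), sub[met].to_numpy(), X,
            sub["family_id"].to_numpy(), mode=mode, seed=seed, k=k,
        )
        rows.append(
            {"cohort": am.cohort, "metabolite": met, "model": model.id,
             "n": n_used, "k": k, "df": df, "r": r, "p": p}
        )
    return pd.DataFrame(rows, columns=["cohort", "metabolite", "model", "n", "k", "df", "r", "p"])
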