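"""Replicated simulation experiments that validate the pipeline's calibration.

These are the package's own operating-characteristic checks, run on reduced
problem sizes chosen so each experiment finishes in minutes on one CPU:

* :func:`fwer_experiment` — family-wise error of the effective-number-of-
  tests threshold under block-correlated null metabolites;
* :func:`recovery_experiment` — recovery of a planted LTL-metabolite partial
  correlation by the full consortium pipeline (generation, QC, family-
  adjusted partial correlation, meta-analysis) at the published cohort sizes
  but on a reduced metabolite panel;
* :func:`cluster_type1_experiment` — type-I error of the partial-correlation
  t test with and without family adjustment under strong family clustering.

Every experiment derives all randomness from a single integer seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .meta import meta_all
from .multiple_testing import veff_li
from .partialcorr import MODEL1, MODEL2, analyze_cohort, partial_corr_family
from .qc import build_analysis_matrix
from .simulate import (
    CohortSpec,
    PanelSpec,
    TrueEffects,
    default_cohort_specs,
    generate_cohort,
    generate_consortium,
    generate_replicates,
    replicate_seed,
)

__all__ = [
    "fwer_experiment",
    "recovery_experiment",
    "cluster_type1_experiment",
    "reduced_recovery_panel",
]


def _spawn(seed: int, tag: int, rep: int) -> int:
    return int(np.random.SeedSequence((seed, tag, rep)).generate_state(1)[0] >> 1)


def fwer_experiment(
    n_replicates: int = 500,
    n: int = 500,
    n_metabolites: int = 20,
    n_blocks: int = 4,
    rho: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Family-wise error of the veff-based threshold under the global null.

    Each replicate draws ``n`` samples of ``n_metabolites`` block-correlated
    null metabolites (no LTL association), estimates the effective number of
    tests from the observed ln-concentration correlation matrix, and tests
    every metabolite against LTL at ``alpha / veff_int`` adjusting for age
    and sex.  Returns the fraction of replicates with at least one rejection.
    """
    per_block = n_metabolites // n_blocks
    names = [f"M{b}_{j}" for b in range(n_blocks) for j in range(per_block)]
    blocks = {f"B{b}": [f"M{b}_{j}" for j in range(per_block)] for b in range(n_blocks)}
    panel = PanelSpec(metabolite_names=names, blocks=blocks, rho_block=rho,
                      log_mean=3.0, log_sd=0.3, lod=0.0, missing_rate=0.0)
    spec = CohortSpec("NULL", n, 50.0, 1.8, 0.3, 50.0, 10.0, family_size_dist={1: 1.0})
    effects = TrueEffects(planted_r={})
    hits = 0
    veffs = []
    for rep in range(n_replicates):
        table = generate_cohort(spec, panel, effects, _spawn(seed, 11, rep))
        reps = generate_replicates(panel, 10, _spawn(seed, 12, rep))
        am, _ = build_analysis_matrix(table, panel.lod.to_dict(), reps)
        corr = am.data[am.metabolites].corr()
        rep_v = veff_li(corr, alpha=alpha)
        veffs.append(rep_v.veff_int)
        res = analyze_cohort(am, MODEL1, family_mode="none")
        if (res["p"] < rep_v.threshold).any():
            hits += 1
    return {
        "fwer": hits / n_replicates,
        "n_replicates": n_replicates,
        "mean_veff_int": float(np.mean(veffs)),
        "alpha": alpha,
    }


def reduced_recovery_panel(planted: str = "lysoPC a C17:0", r: float = 0.05):
    """Eight-metabolite two-block panel with one planted association."""
    aa = ["Met", "Tyr", "Gly", "Ser"]
    lyso = ["lysoPC a C16:0", "lysoPC a C17:0", "lysoPC a C18:0", "lysoPC a C18:1"]
    panel = PanelSpec(
        metabolite_names=aa + lyso,
        blocks={"AA": aa, "lysoPC": lyso},
        rho_block={"AA": 0.3, "lysoPC": 0.5},
        log_mean={**{m: math.log(120.0) for m in aa}, **{m: math.log(25.0) for m in lyso}},
        log_sd=0.3,
        lod={**{m: 1.0 for m in aa}, **{m: 0.05 for m in lyso}},
        missing_rate=0.005,
    )
    effects = TrueEffects(planted_r={planted: r})
    return panel, effects, planted


def recovery_experiment(
    n_replicates: int = 100,
    planted_r: float = 0.05,
    tolerance: float = 0.025,
    seed: int = 0,
    specs: list[CohortSpec] | None = None,
) -> dict:
    """Recovery of a planted partial correlation by the full pipeline.

    Runs the whole chain — seven-cohort generation at the published sample
    sizes (family clustering included), missingness/LOD injection, QC,
    family-adjusted partial correlation (mixed_residual), fixed-effect
    pooling — on a reduced eight-metabolite panel, and measures how often
    the pooled estimate lands within ``tolerance`` of the planted value.

    The planted correlation is defined conditional on age, sex and BMI, so
    the estimand-matched estimator is the fully adjusted model; the cohort
    without BMI drops out of it, leaving a pooled n of ~7,700.
    """
    specs = default_cohort_specs() if specs is None else specs
    panel, effects, planted = reduced_recovery_panel(r=planted_r)
    estimates = []
    for rep in range(n_replicates):
        rep_master = _spawn(seed, 21, rep)
        cohorts = generate_consortium(specs, panel, effects, rep_master, inject=True,
                                      censor_lod=False)
        frames = []
        for i, table in enumerate(cohorts):
            qc_reps = generate_replicates(panel, 10, replicate_seed(rep_master, i))
            am, _ = build_analysis_matrix(table, panel.lod.to_dict(), qc_reps)
            if not am.has_bmi:
                continue
            frames.append(analyze_cohort(am, MODEL2, family_mode="mixed_residual"))
        pooled = meta_all(pd.concat(frames, ignore_index=True), [s.name for s in specs])
        row = pooled.set_index("metabolite").loc[planted]
        estimates.append(float(row["r"]))
    estimates = np.asarray(estimates)
    within = np.abs(estimates - planted_r) <= tolerance
    return {
        "recovery_rate": float(within.mean()),
        "mean_estimate": float(estimates.mean()),
        "sd_estimate": float(estimates.std(ddof=1)),
        "n_replicates": n_replicates,
        "planted_r": planted_r,
        "tolerance": tolerance,
        "pooled_n": int(sum(s.n for s in specs if s.bmi_mean is not None)),
    }


def cluster_type1_experiment(
    n_replicates: int = 500,
    n_families: int = 200,
    family_size: int = 4,
    icc: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the partial-correlation test under family clustering.

    x and y share no association but each carries a family random intercept
    of intra-class correlation ``icc``.  Compares the naive test (families
    ignored) with mixed_residual adjustment at level ``alpha``.
    """
    n = n_families * family_size
    fam = np.repeat(np.arange(n_families), family_size)
    rej = {"none": 0, "mixed_residual": 0}
    rng_master = np.random.SeedSequence((seed, 31))
    for rep, child in enumerate(rng_master.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        Z = rng.standard_normal((n, 2))  # age- and sex-like covariates
        ux = rng.standard_normal(n_families)
        uy = rng.standard_normal(n_families)
        x = 0.2 * Z[:, 0] + math.sqrt(icc) * ux[fam] + math.sqrt(1 - icc) * rng.standard_normal(n)
        y = 0.2 * Z[:, 1] + math.sqrt(icc) * uy[fam] + math.sqrt(1 - icc) * rng.standard_normal(n)
        X = np.column_stack([np.ones(n), Z])
        for mode in rej:
            _, _, _, p = partial_corr_family(x, y, X, fam, mode=mode)
            if p < alpha:
                rej[mode] += 1
    return {
        "type1_none": rej["none"] / n_replicates,
        "type1_mixed": rej["mixed_residual"] / n_replicates,
        "n_replicates": n_replicates,
        "alpha": alpha,
    }
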