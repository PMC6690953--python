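"""Per-cohort metabolite quality control and analysis-ready transforms.

A metabolite enters the analysis in a given cohort only if it meets all three
assay-quality criteria there:

1. coefficient of variation (CV) of replicate QC-sample measurements not
   exceeding 25% (``cv <= 0.25``);
2. less than 5% missing values (``missing_fraction < 0.05``);
3. median of the observed concentrations strictly above the limit of
   detection (``median > lod``).

QC verdicts are per cohort; the report lists every triggered reason.  Kept
concentrations are natural-log transformed, and LTL is Z-scored within cohort
so that the per-cohort correlations are comparable across cohorts measured on
different qPCR scales.  Missing values are left missing (available-case
analysis downstream), never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import CohortTable

__all__ = [
    "QC_CV_MAX",
    "QC_MISSING_MAX",
    "compute_cv",
    "apply_qc",
    "ln_transform",
    "z_transform_ltl",
    "AnalysisMatrix",
    "build_analysis_matrix",
    "write_qc_report",
]

QC_CV_MAX = 0.25
QC_MISSING_MAX = 0.05


def compute_cv(values) -> float:
    """Coefficient of variation sd/mean of replicate measurements.

    Uses the sample standard deviation (n-1 denominator).  Requires at least
    two non-missing replicates and a strictly positive mean.
    """
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size < 2:
        raise ValueError("compute_cv requires at least 2 non-missing replicate values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError(f"compute_cv requires a positive mean, got {mean!r}")
    return float(arr.std(ddof=1) / mean)


def apply_qc(
    table: CohortTable,
    lods: Mapping[str, float],
    replicates: pd.DataFrame,
    cv_max: float = QC_CV_MAX,
    missing_max: float = QC_MISSING_MAX,
) -> tuple[CohortTable, pd.DataFrame]:
    """Apply the three QC criteria to one cohort.

    ``replicates`` is a table of QC-sample replicate measurements with one
    column per metabolite (extra non-metabolite columns are ignored), from
    which the CVs are computed.  Returns the cohort restricted to kept
    metabolites and a report with one row per metabolite (columns:
    metabolite, cv, missing_fraction, median, lod, verdict, reasons).

    Boundary semantics: ``cv == cv_max`` passes ("not exceeding"),
    ``missing_fraction == missing_max`` fails ("less than"), and a median
    exactly equal to the LOD fails ("above").
    """
    rows = []
    kept = []
    for met in table.metabolites:
        if met not in lods:
            raise ValueError(f"no LOD supplied for metabolite {met!r}")
        if met not in replicates.columns:
            raise ValueError(f"no replicate measurements for metabolite {met!r}")
        cv = compute_cv(replicates[met])
        col = table.data[met]
        missing_fraction = float(col.isna().mean())
        median = float(col.median()) if col.notna().any() else np.nan
        lod = float(lods[met])
        reasons = []
        if cv > cv_max:
            reasons.append("CV")
        if missing_fraction >= missing_max:
            reasons.append("missingness")
        if not (median > lod):  # NaN median also fails
            reasons.append("LOD")
        verdict = "kept" if not reasons else "excluded"
        if not reasons:
            kept.append(met)
        rows.append(
            {
                "metabolite": met,
                "cv": cv,
                "missing_fraction": missing_fraction,
                "median": median,
                "lod": lod,
                "verdict": verdict,
                "reasons": ";".join(reasons),
            }
        )
    report = pd.DataFrame(rows)
    pheno = [c for c in table.data.columns if c not in table.metabolites]
    kept_table = CohortTable(table.name, table.data[pheno + kept].copy(), kept)
    return kept_table, report


def ln_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise natural log; missing stays missing; values <= 0 are errors."""
    bad = matrix.le(0.0)
    if bad.any().any():
        met = bad.any().idxmax()
        sample = bad[met].idxmax()
        raise ValueError(
            f"ln_transform requires positive concentrations: metabolite {met!r}, row {sample!r}"
        )
    return np.log(matrix)


def z_transform_ltl(ltl) -> pd.Series:
    """Within-cohort Z-score (x - mean) / sd, sample sd with n-1 denominator."""
    s = pd.Series(ltl, dtype=float)
    if s.dropna().nunique() < 2:
        raise ValueError("z_transform_ltl requires at least 2 distinct LTL values")
    return (s - s.mean()) / s.std(ddof=1)


@dataclass
class AnalysisMatrix:
    """Analysis-ready matrix for one cohort.

    ``data`` columns: sample_id, family_id, ltl_z, age, sex (0 = M, 1 = F),
    bmi (absent for cohorts without BMI), then one natural-log concentration
    column per kept metabolite.
    """

    cohort: str
    data: pd.DataFrame
    metabolites: list[str]

    @property
    def has_bmi(self) -> bool:
        return "bmi" in self.data.columns and self.data["bmi"].notna().any()


def build_analysis_matrix(
    table: CohortTable,
    lods: Mapping[str, float],
    replicates: pd.DataFrame,
    cv_max: float = QC_CV_MAX,
    missing_max: float = QC_MISSING_MAX,
) -> tuple[AnalysisMatrix, pd.DataFrame]:
    """QC one cohort then assemble Z-scored LTL, covariates and ln-metabolites.

    QC judges the reported concentrations; afterwards any kept value below
    its metabolite's LOD is censored to missing (never imputed) before the
    log transform.
    """
    kept_table, report = apply_qc(table, lods, replicates, cv_max=cv_max, missing_max=missing_max)
    df = kept_table.data
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "family_id": df["family_id"],
            "ltl_z": z_transform_ltl(df["ltl"]),
            "age": df["age"].astype(float),
            "sex": (df["sex"].astype(str) == "F").astype(float),
        }
    )
    if "bmi" in df.columns:
        out["bmi"] = df["bmi"].astype(float)
    conc = kept_table.concentrations().copy()
    for met in kept_table.metabolites:
        conc.loc[conc[met] < float(lods[met]), met] = np.nan
    ln = ln_transform(conc)
    out = pd.concat([out, ln], axis=1)
    return AnalysisMatrix(table.name, out, list(kept_table.metabolites)), report


def write_qc_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, na_rep="NA")
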