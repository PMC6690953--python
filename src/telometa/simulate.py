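"""Synthetic multi-cohort consortium generator.

The real consortium data (seven population-based cohorts with leukocyte
telomere length, covariates and a ~131-metabolite targeted serum panel) are
access-restricted, so every downstream stage of the pipeline is exercised on
synthetic cohorts that reproduce the statistical structure the analysis
assumes:

* per-cohort demographics (sample size, % female, LTL / age / BMI means and
  SDs) matching the published cohort descriptions;
* family clustering (twins, sibships) as non-overlapping clusters sharing a
  Gaussian random intercept, with a single intra-class-correlation knob;
* log-normal metabolite concentrations with block correlation within
  metabolite classes and confounder loadings of age / sex / BMI;
* planted partial correlations between LTL and selected metabolites, given
  age, sex and BMI, of the small magnitudes (|r| ~ 0.03-0.10) the analysis is
  powered to detect;
* missing-completely-at-random dropout and below-LOD censoring, plus a
  replicate (QC-sample) table from which assay CVs are estimated.

All randomness flows from integer seeds.  A consortium derives one seed per
cohort from the master seed with a counter scheme (see
:func:`consortium_seeds`), so appending a cohort never perturbs the ones
already generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortSpec",
    "PanelSpec",
    "TrueEffects",
    "CohortTable",
    "generate_cohort",
    "inject_missing_and_lod",
    "generate_consortium",
    "generate_replicates",
    "consortium_seeds",
    "replicate_seed",
    "default_panel",
    "default_cohort_specs",
    "default_effects",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "write_consortium",
]

#: Fixed non-metabolite columns of a cohort TSV, in order.
PHENOTYPE_COLUMNS = ("sample_id", "family_id", "ltl", "age", "sex", "bmi")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid field '{name}': {msg}")


@dataclass
class CohortSpec:
    """Demographic description of one cohort.

    ``ltl_mean``/``ltl_sd`` are on the T/S-ratio scale, ``age`` in years and
    ``bmi`` in kg/m^2.  ``bmi_mean``/``bmi_sd`` may be ``None`` for a cohort
    where BMI was not assessed; ``n_bmi`` is the number of participants with
    BMI available (defaults to ``n``).  ``family_size_dist`` maps cluster size
    to probability; ``family_icc`` is the intra-family correlation of the LTL
    and metabolite random components.
    """

    name: str
    n: int
    pct_female: float
    ltl_mean: float
    ltl_sd: float
    age_mean: float
    age_sd: float
    bmi_mean: float | None = None
    bmi_sd: float | None = None
    n_bmi: int | None = None
    family_size_dist: Mapping[int, float] = field(default_factory=lambda: {1: 1.0})
    family_icc: float = 0.0

    def validate(self) -> None:
        _require(self.n >= 1, "n", "sample count must be >= 1")
        _require(0.0 <= self.pct_female <= 100.0, "pct_female", "must be in [0, 100]")
        _require(self.ltl_sd > 0, "ltl_sd", "must be > 0")
        _require(self.age_sd > 0, "age_sd", "must be > 0")
        if (self.bmi_mean is None) != (self.bmi_sd is None):
            raise ValueError("invalid field 'bmi_sd': bmi_mean and bmi_sd must be given together")
        if self.bmi_sd is not None:
            _require(self.bmi_sd > 0, "bmi_sd", "must be > 0")
        if self.n_bmi is not None:
            _require(0 <= self.n_bmi <= self.n, "n_bmi", "must be in [0, n]")
        _require(0.0 <= self.family_icc < 1.0, "family_icc", "must be in [0, 1)")
        sizes = list(self.family_size_dist)
        probs = [self.family_size_dist[s] for s in sizes]
        _require(len(sizes) > 0, "family_size_dist", "must be non-empty")
        _require(all(int(s) >= 1 for s in sizes), "family_size_dist", "cluster sizes must be >= 1")
        _require(all(p >= 0 for p in probs), "family_size_dist", "probabilities must be >= 0")
        _require(abs(sum(probs) - 1.0) < 1e-8, "family_size_dist", "probabilities must sum to 1")

    @property
    def has_bmi(self) -> bool:
        return self.bmi_mean is not None


@dataclass
class PanelSpec:
    """Targeted metabolite panel: names, correlation blocks and assay model.

    Per-metabolite fields (``log_mean``, ``log_sd``, ``lod``, ``missing_rate``,
    ``cv_true``) may be supplied as scalars (applied to every metabolite) or as
    mappings; they are normalised to :class:`pandas.Series` keyed by metabolite
    name.  ``blocks`` partitions the metabolites into correlated classes;
    ``rho_block`` is the within-block correlation of the residual (covariate-
    and LTL-independent) component on the log scale.
    """

    metabolite_names: list[str]
    blocks: Mapping[str, Sequence[str]]
    rho_block: float | Mapping[str, float] = 0.4
    log_mean: float | Mapping[str, float] = 3.0
    log_sd: float | Mapping[str, float] = 0.3
    lod: float | Mapping[str, float] = 0.0
    missing_rate: float | Mapping[str, float] = 0.0
    cv_true: float | Mapping[str, float] = 0.08

    def __post_init__(self) -> None:
        names = list(self.metabolite_names)
        for f in ("log_mean", "log_sd", "lod", "missing_rate", "cv_true"):
            setattr(self, f, _as_series(getattr(self, f), names, f))
        if not isinstance(self.rho_block, Mapping):
            self.rho_block = {b: float(self.rho_block) for b in self.blocks}

    def validate(self) -> None:
        names = list(self.metabolite_names)
        _require(len(names) == len(set(names)), "metabolite_names", "duplicate names")
        members = [m for b in self.blocks.values() for m in b]
        _require(sorted(members) == sorted(names), "blocks", "must partition metabolite_names")
        for b, rho in self.rho_block.items():
            _require(abs(rho) < 1.0, "rho_block", f"|rho| must be < 1 (block {b!r})")
        _require(bool((self.lod >= 0).all()), "lod", "must be >= 0")
        _require(
            bool(((self.missing_rate >= 0) & (self.missing_rate < 1)).all()),
            "missing_rate",
            "must be in [0, 1)",
        )
        _require(bool((self.log_sd > 0).all()), "log_sd", "must be > 0")
        _require(bool((self.cv_true > 0).all()), "cv_true", "must be > 0")

    def block_of(self) -> pd.Series:
        """Metabolite -> block-name lookup."""
        return pd.Series({m: b for b, mets in self.blocks.items() for m in mets})


@dataclass
class TrueEffects:
    """Planted structure linking LTL, covariates and metabolites.

    ``planted_r`` maps metabolite name to the partial correlation with LTL
    given age, sex and BMI; metabolites not listed get 0.  The loading dicts
    give standardized linear effects of the covariates on the LTL latent and
    (uniformly) on every log-metabolite.
    """

    planted_r: Mapping[str, float] = field(default_factory=dict)
    ltl_loadings: Mapping[str, float] = field(
        default_factory=lambda: {"age": -0.30, "sex": 0.05, "bmi": -0.03}
    )
    met_loadings: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.15, "sex": 0.10, "bmi": 0.08}
    )

    def validate(self) -> None:
        for m, r in self.planted_r.items():
            _require(abs(r) < 1.0, "planted_r", f"|r| must be < 1 (metabolite {m!r})")
        for name, load in (("ltl_loadings", self.ltl_loadings), ("met_loadings", self.met_loadings)):
            s2 = sum(v * v for v in load.values())
            _require(s2 < 1.0, name, "sum of squared loadings must be < 1")


@dataclass
class CohortTable:
    """One cohort: phenotypes plus a metabolite concentration matrix (uM).

    ``data`` holds the columns of :data:`PHENOTYPE_COLUMNS` (``bmi`` absent for
    cohorts without BMI) followed by one column per metabolite; missing
    concentrations are ``NaN``.
    """

    name: str
    data: pd.DataFrame
    metabolites: list[str]

    @property
    def n(self) -> int:
        return len(self.data)

    def concentrations(self) -> pd.DataFrame:
        return self.data[self.metabolites]


def _as_series(value, names: list[str], fieldname: str) -> pd.Series:
    if isinstance(value, pd.Series):
        s = value.reindex(names)
    elif isinstance(value, Mapping):
        s = pd.Series(value, dtype=float).reindex(names)
    else:
        s = pd.Series(float(value), index=names)
    if s.isna().any():
        missing = list(s.index[s.isna()])[:3]
        raise ValueError(f"invalid field '{fieldname}': no value for metabolites {missing}")
    return s.astype(float)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_family_sizes(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    sizes = np.array(sorted(spec.family_size_dist), dtype=int)
    probs = np.array([spec.family_size_dist[int(s)] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    out: list[int] = []
    total = 0
    while total < spec.n:
        s = int(rng.choice(sizes, p=probs))
        s = min(s, spec.n - total)  # truncate the last cluster so sizes sum to n
        out.append(s)
        total += s
    return np.array(out, dtype=int)


def _standardize_sex(sex_is_female: np.ndarray, p: float) -> np.ndarray:
    if p <= 0.0 or p >= 1.0:
        return np.zeros(sex_is_female.shape)
    return (sex_is_female.astype(float) - p) / math.sqrt(p * (1.0 - p))


def generate_cohort(
    spec: CohortSpec, panel: PanelSpec, effects: TrueEffects, seed: int
) -> CohortTable:
    """Draw one cohort from the joint Gaussian latent model.

    LTL and log-concentrations share a latent structure: covariate loadings,
    a family random intercept (weight ``sqrt(family_icc)``) and, for planted
    metabolites, a common component giving the requested partial correlation
    with LTL conditional on the covariates.  Concentrations are exponentiated
    to the uM scale.  The same ``(spec, panel, effects, seed)`` always yields
    a byte-identical table.
    """
    spec.validate()
    panel.validate()
    effects.validate()
    rng = np.random.default_rng(seed)
    n = spec.n

    fam_sizes = _draw_family_sizes(rng, spec)
    fam_index = np.repeat(np.arange(len(fam_sizes)), fam_sizes)

    age = rng.normal(spec.age_mean, spec.age_sd, n)
    female = rng.random(n) < spec.pct_female / 100.0
    bmi = rng.normal(spec.bmi_mean, spec.bmi_sd, n) if spec.has_bmi else None

    age_z = (age - spec.age_mean) / spec.age_sd
    sex_c = _standardize_sex(female, spec.pct_female / 100.0)
    bmi_z = (bmi - spec.bmi_mean) / spec.bmi_sd if spec.has_bmi else None

    icc = spec.family_icc
    u_fam = rng.standard_normal(len(fam_sizes))  # LTL family intercept
    v_fam = rng.standard_normal(len(fam_sizes))  # metabolite family intercept
    eps_ltl = math.sqrt(icc) * u_fam[fam_index] + math.sqrt(1.0 - icc) * rng.standard_normal(n)

    ltl_lin, s2 = _covariate_part(effects.ltl_loadings, age_z, sex_c, bmi_z)
    ltl = spec.ltl_mean + spec.ltl_sd * (ltl_lin + math.sqrt(1.0 - s2) * eps_ltl)

    block_names = list(panel.blocks)
    g_block = {b: rng.standard_normal(n) for b in block_names}
    met_lin, s2m = _covariate_part(effects.met_loadings, age_z, sex_c, bmi_z)

    conc = {}
    for b in block_names:
        rho = panel.rho_block[b]
        for met in panel.blocks[b]:
            h = rng.standard_normal(n)
            w = math.sqrt(icc) * v_fam[fam_index] + math.sqrt(1.0 - icc) * (
                math.sqrt(abs(rho)) * np.sign(rho) * g_block[b] + math.sqrt(1.0 - abs(rho)) * h
            )
            r = float(effects.planted_r.get(met, 0.0))
            resid = r * eps_ltl + math.sqrt(1.0 - r * r) * w
            z = met_lin + math.sqrt(1.0 - s2m) * resid
            conc[met] = np.exp(panel.log_mean[met] + panel.log_sd[met] * z)

    width = len(str(n))
    data = pd.DataFrame(
        {
            "sample_id": [f"{spec.name}_{i + 1:0{width}d}" for i in range(n)],
            "family_id": [f"{spec.name}_F{f + 1:0{width}d}" for f in fam_index],
            "ltl": ltl,
            "age": age,
            "sex": np.where(female, "F", "M"),
        }
    )
    if spec.has_bmi:
        bmi_out = np.asarray(bmi, dtype=float).copy()
        n_bmi = spec.n if spec.n_bmi is None else spec.n_bmi
        if n_bmi < n:
            drop = rng.choice(n, size=n - n_bmi, replace=False)
            bmi_out[drop] = np.nan
        data["bmi"] = bmi_out
    data = pd.concat([data, pd.DataFrame({m: conc[m] for m in panel.metabolite_names})], axis=1)
    return CohortTable(name=spec.name, data=data, metabolites=list(panel.metabolite_names))


def _covariate_part(loadings: Mapping[str, float], age_z, sex_c, bmi_z):
    parts = {"age": age_z, "sex": sex_c, "bmi": bmi_z}
    lin = 0.0
    s2 = 0.0
    for cov, load in loadings.items():
        x = parts.get(cov)
        if x is None:
            continue  # cohort without BMI: loading dropped, variance renormalised
        lin = lin + load * x
        s2 += load * load
    return lin, s2


def inject_missing_and_lod(
    table: CohortTable, panel: PanelSpec, seed: int, censor_lod: bool = True
) -> tuple[CohortTable, pd.DataFrame]:
    """MCAR dropout at ``missing_rate`` plus optional below-LOD censoring.

    Values below the metabolite's limit of detection are set missing rather
    than imputed.  ``censor_lod=False`` applies the MCAR dropout only, for
    workflows where the QC stage must see the reported raw values (its
    median-above-LOD rule judges the uncensored distribution) and censoring
    is applied when the analysis matrix is built.  Returns the table and a
    per-metabolite count report (``n_missing``, ``n_below_lod``).
    """
    rng = np.random.default_rng(seed)
    data = table.data.copy()
    rows = []
    for met in table.metabolites:
        rate = float(panel.missing_rate[met])
        lod = float(panel.lod[met])
        col = data[met].to_numpy(dtype=float, copy=True)
        mask = rng.random(len(col)) < rate
        col[mask] = np.nan
        below = ~np.isnan(col) & (col < lod)
        if censor_lod:
            col[below] = np.nan
        data[met] = col
        rows.append({"metabolite": met, "n_missing": int(mask.sum()), "n_below_lod": int(below.sum())})
    report = pd.DataFrame(rows)
    return CohortTable(table.name, data, list(table.metabolites)), report


def generate_replicates(panel: PanelSpec, n_replicates: int, seed: int) -> pd.DataFrame:
    """QC-sample replicate measurements used to estimate per-metabolite CV.

    Each metabolite is measured ``n_replicates`` times on a reference sample;
    replicates are log-normal with geometric mean ``exp(log_mean)`` and a log
    SD chosen so the concentration-scale CV equals ``cv_true``.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    out = {}
    for met in panel.metabolite_names:
        sdlog = math.sqrt(math.log1p(float(panel.cv_true[met]) ** 2))
        out[met] = np.exp(panel.log_mean[met] + sdlog * rng.standard_normal(n_replicates))
    df = pd.DataFrame(out)
    df.insert(0, "replicate_id", [f"QC_{i + 1:02d}" for i in range(n_replicates)])
    return df


def consortium_seeds(master_seed: int, n_cohorts: int) -> list[int]:
    """Per-cohort seeds: ``SeedSequence((master_seed, index))`` -> 31-bit int.

    Counter-keyed derivation, so seeds for cohorts 0..k-1 are unchanged when a
    k+1-th cohort is appended.
    """
    return [
        int(np.random.SeedSequence((master_seed, i)).generate_state(1)[0] >> 1)
        for i in range(n_cohorts)
    ]


def replicate_seed(master_seed: int, index: int) -> int:
    """Seed for cohort ``index``'s replicate table (counter stream 1)."""
    return int(np.random.SeedSequence((master_seed, index, 1)).generate_state(1)[0] >> 1)


def generate_consortium(
    specs: Sequence[CohortSpec],
    panel: PanelSpec,
    effects: TrueEffects,
    seed: int,
    inject: bool = False,
    censor_lod: bool = True,
) -> list[CohortTable]:
    """Generate independent cohorts with seeds derived from ``seed``.

    With ``inject=True``, MCAR missingness (and, unless ``censor_lod`` is
    off, below-LOD censoring) is applied to each cohort, seeded from the same
    counter scheme (stream 2).
    """
    if len(specs) == 0:
        raise ValueError("at least one cohort spec is required")
    names = [s.name for s in specs]
    if len(names) != len(set(names)):
        raise ValueError(f"duplicate cohort names: {sorted({n for n in names if names.count(n) > 1})}")
    seeds = consortium_seeds(seed, len(specs))
    cohorts = []
    for i, spec in enumerate(specs):
        table = generate_cohort(spec, panel, effects, seeds[i])
        if inject:
            inj_seed = int(np.random.SeedSequence((seed, i, 2)).generate_state(1)[0] >> 1)
            table, _ = inject_missing_and_lod(table, panel, inj_seed, censor_lod=censor_lod)
        cohorts.append(table)
    return cohorts


# ---------------------------------------------------------------------------
# defaults: the study conditions
# ---------------------------------------------------------------------------

_AA = ["Arg", "Gln", "Gly", "His", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val", "xLeu"]
_AC = [
    "C0", "C2", "C3", "C3-OH", "C4", "C5", "C5-OH", "C6", "C6:1", "C8", "C9",
    "C10", "C10:1", "C12", "C14", "C14:1", "C16", "C16:1", "C18", "C18:1", "C18:2",
]
_SM = [
    "SM C16:0", "SM C16:1", "SM C18:0", "SM C18:1", "SM C20:2", "SM C22:3",
    "SM C24:0", "SM C24:1", "SM C26:0", "SM C26:1", "SM (OH) C14:1",
    "SM (OH) C16:1", "SM (OH) C22:1", "SM (OH) C22:2", "SM (OH) C24:1",
]
_LYSOPC = [
    "lysoPC a C16:0", "lysoPC a C16:1", "lysoPC a C17:0", "lysoPC a C18:0",
    "lysoPC a C18:1", "lysoPC a C18:2", "lysoPC a C20:4", "lysoPC a C28:1",
]
_PC_AA = [
    "C24:0", "C26:0", "C28:1", "C30:0", "C32:0", "C32:1", "C32:2", "C32:3",
    "C34:1", "C34:2", "C34:3", "C34:4", "C36:0", "C36:1", "C36:2", "C36:3",
    "C36:4", "C36:5", "C36:6", "C38:0", "C38:1", "C38:3", "C38:4", "C38:5",
    "C38:6", "C40:2", "C40:3", "C40:4", "C40:5", "C40:6", "C42:0", "C42:1",
    "C42:2", "C42:4", "C42:5", "C42:6",
]
_PC_AE = [
    "C30:0", "C30:1", "C32:1", "C32:2", "C34:0", "C34:1", "C34:2", "C34:3",
    "C36:0", "C36:1", "C36:2", "C36:3", "C36:4", "C36:5", "C38:0", "C38:1",
    "C38:2", "C38:3", "C38:4", "C38:5", "C38:6", "C40:1", "C40:2", "C40:3",
    "C40:4", "C40:5", "C40:6", "C42:1", "C42:2", "C42:3", "C42:4", "C42:5",
    "C44:3", "C44:4", "C44:5", "C44:6",
]


def default_panel() -> PanelSpec:
    """131-metabolite targeted serum panel with class-wise correlation blocks.

    Class composition (hexose; amino acids; acylcarnitines; sphingomyelins;
    lysoPCs; diacyl and acyl-alkyl phosphatidylcholines) mirrors a Biocrates
    p150-style assay after quality control.  Typical-concentration log means,
    within-class correlations, LODs and a small MCAR rate are chosen as
    realistic defaults for serum.
    """
    blocks = {
        "H1": ["H1"],
        "AA": list(_AA),
        "AC": list(_AC),
        "SM": list(_SM),
        "lysoPC": list(_LYSOPC),
        "PC aa": [f"PC aa {c}" for c in _PC_AA],
        "PC ae": [f"PC ae {c}" for c in _PC_AE],
    }
    names = [m for b in blocks.values() for m in b]
    class_log_mean = {"H1": math.log(4500.0), "AA": math.log(120.0), "AC": math.log(0.15),
                      "SM": math.log(60.0), "lysoPC": math.log(25.0), "PC aa": math.log(30.0),
                      "PC ae": math.log(4.0)}
    class_lod = {"H1": 20.0, "AA": 1.0, "AC": 0.01, "SM": 0.05, "lysoPC": 0.05,
                 "PC aa": 0.05, "PC ae": 0.02}
    # within-class correlations calibrated so the metabolome-wide effective
    # number of independent tests in a reference-size cohort comes out near
    # the published value (~46 of 131)
    rho = {"H1": 0.0, "AA": 0.30, "AC": 0.45, "SM": 0.55, "lysoPC": 0.55,
           "PC aa": 0.60, "PC ae": 0.60}
    block_of = {m: b for b, mets in blocks.items() for m in mets}
    return PanelSpec(
        metabolite_names=names,
        blocks=blocks,
        rho_block=rho,
        log_mean={m: class_log_mean[block_of[m]] for m in names},
        log_sd=0.30,
        lod={m: class_lod[block_of[m]] for m in names},
        missing_rate=0.005,
        cv_true=0.08,
    )


def default_cohort_specs() -> list[CohortSpec]:
    """The seven published cohort descriptions (n, % female, LTL/age/BMI).

    Twin-register cohorts get mostly 1-2-person clusters and the family-based
    cohorts larger sibships; intra-family correlation is 0 for the unrelated
    population samples and 0.3-0.4 for the family designs.  One cohort (QIMR)
    has no BMI.
    """
    twins = {1: 0.3, 2: 0.7}
    sibs = {1: 0.2, 2: 0.3, 3: 0.3, 4: 0.2}
    singles = {1: 1.0}
    return [
        CohortSpec("KORA", 3003, 51.8, 1.85, 0.33, 56.08, 13.25, 27.61, 4.80, n_bmi=2988,
                   family_size_dist=singles, family_icc=0.0),
        CohortSpec("NTR", 1314, 33.3, 2.54, 0.47, 50.60, 14.13, 25.97, 3.80, n_bmi=1307,
                   family_size_dist=twins, family_icc=0.4),
        CohortSpec("EGCUT", 1084, 50.3, 1.90, 0.30, 37.78, 15.70, 25.16, 4.56,
                   family_size_dist=singles, family_icc=0.0),
        CohortSpec("TwinsUK", 810, 100.0, 3.58, 0.64, 53.72, 10.76, 26.44, 5.35,
                   family_size_dist=twins, family_icc=0.4),
        CohortSpec("ERF", 806, 53.7, 1.79, 0.37, 47.76, 13.97, 27.17, 4.81,
                   family_size_dist=sibs, family_icc=0.3),
        CohortSpec("LLS", 643, 50.1, 1.44, 0.27, 62.91, 6.61, 26.65, 4.01,
                   family_size_dist=sibs, family_icc=0.3),
        CohortSpec("QIMR", 193, 48.2, 3.43, 0.56, 18.44, 12.65, None, None,
                   family_size_dist=twins, family_icc=0.4),
    ]


def default_effects() -> TrueEffects:
    """Planted LTL-metabolite partial correlations at the published magnitudes."""
    return TrueEffects(
        planted_r={
            "lysoPC a C17:0": 0.05,
            "Met": -0.04,
            "Tyr": -0.04,
            "PC aa C32:1": -0.04,
            "C3-OH": -0.10,
            "PC ae C38:4": 0.04,
        }
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_cohort_tsv(table: CohortTable, path) -> None:
    """One TSV per cohort; missing values are empty fields."""
    table.data.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort_tsv(path, name: str | None = None) -> CohortTable:
    """Read a cohort TSV in the dialect written by :func:`write_cohort_tsv`.

    Metabolite columns are everything after the fixed phenotype columns; the
    ``bmi`` column may be absent.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family_id": str, "sex": str})
    fixed = [c for c in PHENOTYPE_COLUMNS if c in df.columns]
    mets = [c for c in df.columns if c not in fixed]
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return CohortTable(name=name, data=df, metabolites=mets)


def write_consortium(
    cohorts: Sequence[CohortTable],
    specs: Sequence[CohortSpec],
    seed: int,
    outdir,
) -> None:
    """Write one TSV per cohort plus a YAML sidecar recording specs and seed."""
    import os
    from dataclasses import asdict

    os.makedirs(outdir, exist_ok=True)
    for table in cohorts:
        write_cohort_tsv(table, os.path.join(outdir, f"{table.name}.tsv"))
    sidecar = {
        "seed": int(seed),
        "cohorts": [asdict(s) for s in specs],
    }
    with open(os.path.join(outdir, "consortium.yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
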