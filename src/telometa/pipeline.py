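"""End-to-end orchestration: simulate -> QC -> correlate -> meta -> correct
-> cluster -> pathway, in one seeded, reproducible run.

A run is described by a :class:`RunConfig` (YAML-serialisable).  Inputs are
either simulated from cohort specs or read from user TSVs in the same
dialect; every stage after ingestion is shared.  All outputs are TSVs ('.'
decimal, scientific notation for p-values) under a run directory::

    cohorts/     simulated cohort TSVs + YAML sidecar (simulation mode)
    qc/          per-cohort QC reports
    percohort/   per-cohort, per-model correlation results
    meta/        pooled results per model
    veff/        effective-number-of-tests report and threshold
    sensitivity/ leave-cohort-out re-analyses
    figures/     heat map + correlogram images with TSV companions
    pathway/     pairwise reaction-path results for significant metabolites
    table2.tsv   combined two-model report
    manifest.yaml  config hash, seed, package/library versions
    run.log      line-oriented, stage-tagged log

Any stage failure aborts the run with the stage name attached.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import correlogram, hclust_order, render_correlogram, render_heatmap
from .describe import table_one
from .meta import meta_all, sensitivity_excluding
from .multiple_testing import bh_adjust, flag_significant, significance_stars, veff_li
from .partialcorr import MODELS, analyze_cohort
from .pathway import default_network, default_synonyms, pairwise_search
from .qc import build_analysis_matrix, write_qc_report
from .simulate import (
    CohortSpec,
    PanelSpec,
    TrueEffects,
    default_cohort_specs,
    default_effects,
    default_panel,
    generate_consortium,
    generate_replicates,
    read_cohort_tsv,
    replicate_seed,
    write_consortium,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_table2", "demo_config", "full_name"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a run needs; ``seed`` is mandatory for simulated input."""

    seed: int
    cohort_specs: list[CohortSpec] = field(default_factory=default_cohort_specs)
    cohort_tsvs: list[str] | None = None  # real-data mode: paths in the synthetic dialect
    panel: PanelSpec = field(default_factory=default_panel)
    effects: TrueEffects = field(default_factory=default_effects)
    models: list[str] = field(default_factory=lambda: ["model1", "model2"])
    family_modes: Mapping[str, str] = field(default_factory=dict)  # cohort -> mode
    default_family_mode: str = "mixed_residual"
    alpha: float = 0.05
    veff_reference: list[str] = field(default_factory=lambda: ["ERF", "NTR"])
    sensitivity_exclude: list[list[str]] = field(default_factory=lambda: [["TwinsUK"], ["QIMR"]])
    n_replicates: int = 20
    make_figures: bool = True
    run_pathway: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}")

    @property
    def cohort_order(self) -> list[str]:
        return [s.name for s in self.cohort_specs]

    def family_mode(self, cohort: str) -> str:
        return self.family_modes.get(cohort, self.default_family_mode)

    def canonical_yaml(self) -> str:
        blob = {
            "seed": self.seed,
            "cohort_specs": [asdict(s) for s in self.cohort_specs],
            "cohort_tsvs": self.cohort_tsvs,
            "panel": {
                "metabolite_names": self.panel.metabolite_names,
                "blocks": {b: list(m) for b, m in self.panel.blocks.items()},
                "rho_block": dict(self.panel.rho_block),
                "log_mean": self.panel.log_mean.to_dict(),
                "log_sd": self.panel.log_sd.to_dict(),
                "lod": self.panel.lod.to_dict(),
                "missing_rate": self.panel.missing_rate.to_dict(),
                "cv_true": self.panel.cv_true.to_dict(),
            },
            "effects": asdict(self.effects),
            "models": self.models,
            "family_modes": dict(self.family_modes),
            "default_family_mode": self.default_family_mode,
            "alpha": self.alpha,
            "veff_reference": self.veff_reference,
            "sensitivity_exclude": self.sensitivity_exclude,
            "n_replicates": self.n_replicates,
        }
        return yaml.safe_dump(blob, sort_keys=True)


def demo_config(seed: int = 1, scale: float = 1.0, n_metabolites: int | None = None) -> RunConfig:
    """The published seven-cohort consortium conditions, optionally scaled down.

    ``scale`` multiplies cohort sizes; ``n_metabolites`` truncates the panel
    (block structure preserved) for quick runs.
    """
    specs = default_cohort_specs()
    if scale != 1.0:
        for s in specs:
            s.n = max(12, int(round(s.n * scale)))
            s.n_bmi = None if s.n_bmi is None else min(s.n, max(10, int(round(s.n_bmi * scale))))
    panel = default_panel()
    if n_metabolites is not None:
        panel = truncate_panel(panel, n_metabolites)
    return RunConfig(seed=seed, cohort_specs=specs, panel=panel)


def truncate_panel(panel: PanelSpec, n_metabolites: int) -> PanelSpec:
    """First ``n_metabolites`` names (keeping planted/default metabolites first
    within their blocks is not attempted; blocks are truncated accordingly)."""
    names = panel.metabolite_names[:n_metabolites]
    keep = set(names)
    blocks = {b: [m for m in mets if m in keep] for b, mets in panel.blocks.items()}
    blocks = {b: mets for b, mets in blocks.items() if mets}
    return PanelSpec(
        metabolite_names=names,
        blocks=blocks,
        rho_block={b: panel.rho_block[b] for b in blocks},
        log_mean=panel.log_mean[names],
        log_sd=panel.log_sd[names],
        lod=panel.lod[names],
        missing_rate=panel.missing_rate[names],
        cv_true=panel.cv_true[names],
    )


# ---------------------------------------------------------------------------


_AA_FULL = {
    "Arg": "Arginine", "Gln": "Glutamine", "Gly": "Glycine", "His": "Histidine",
    "Met": "Methionine", "Orn": "Ornithine", "Phe": "Phenylalanine", "Pro": "Proline",
    "Ser": "Serine", "Thr": "Threonine", "Trp": "Tryptophan", "Tyr": "Tyrosine",
    "Val": "Valine", "xLeu": "Leucine/Isoleucine",
}
_AC_FULL = {"C0": "Carnitine", "C2": "Acetylcarnitine", "C3": "Propionylcarnitine",
            "C3-OH": "Hydroxypropionylcarnitine", "C9": "Nonaylcarnitine"}


def full_name(metabolite: str) -> str:
    """Human-readable metabolite name from the panel short name."""
    if metabolite in _AA_FULL:
        return _AA_FULL[metabolite]
    if metabolite in _AC_FULL:
        return _AC_FULL[metabolite]
    if metabolite == "H1":
        return "Hexose"
    if metabolite.startswith("PC aa "):
        return "Phosphatidylcholine diacyl " + metabolite[6:]
    if metabolite.startswith("PC ae "):
        return "Phosphatidylcholine acyl-alkyl " + metabolite[6:]
    if metabolite.startswith("lysoPC a "):
        return "Lysophosphatidylcholine acyl " + metabolite[9:]
    if metabolite.startswith("SM (OH) "):
        return "Hydroxysphingomyeline " + metabolite[8:]
    if metabolite.startswith("SM "):
        return "Sphingomyeline " + metabolite[3:]
    if metabolite.startswith("C") and metabolite[1:2].isdigit():
        return "Acylcarnitine " + metabolite
    return metabolite


def make_table2(
    meta_by_model: Mapping[str, pd.DataFrame],
    threshold: float,
    name_map=full_name,
) -> pd.DataFrame:
    """Combined two-model report sorted by model-1 p (ties by metabolite name).

    Requires pooled results (with fdr) for model1 and model2.  The
    ``significant`` column flags rows passing the family-wise threshold in
    model 1 (strict '<').
    """
    for m in ("model1", "model2"):
        if m not in meta_by_model:
            raise ValueError(f"make_table2 requires pooled results for {m!r}")
    m1 = meta_by_model["model1"].set_index("metabolite")
    m2 = meta_by_model["model2"].set_index("metabolite")
    rows = []
    for met in m1.index:
        row = {"metabolite": met}
        for tag, frame in (("m1", m1), ("m2", m2)):
            if met in frame.index:
                row[f"n_{tag}"] = int(frame.loc[met, "n"])
                row[f"direction_{tag}"] = frame.loc[met, "direction"]
                row[f"r_{tag}"] = float(frame.loc[met, "r"])
                row[f"p_{tag}"] = float(frame.loc[met, "p"])
                row[f"fdr_{tag}"] = float(frame.loc[met, "fdr"])
            else:
                row.update({f"n_{tag}": 0, f"direction_{tag}": "", f"r_{tag}": np.nan,
                            f"p_{tag}": np.nan, f"fdr_{tag}": np.nan})
        row["significant"] = bool(row["p_m1"] < threshold)
        row["full_name"] = name_map(met)
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["p_m1", "metabolite"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.8g")


def run_pipeline(config: RunConfig, outdir: str) -> str:
    """Execute the full analysis; returns the run directory path."""
    os.makedirs(outdir, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    log(name, f"FAILED: {exc}")
                    with open(os.path.join(outdir, "run.log"), "w") as fh:
                        fh.write("\n".join(log_lines) + "\n")
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    panel = config.panel
    with _stage("simulate"):
        if config.cohort_tsvs:
            cohorts = [read_cohort_tsv(p) for p in config.cohort_tsvs]
            log("simulate", f"loaded {len(cohorts)} cohort TSVs")
        else:
            cohorts = generate_consortium(
                config.cohort_specs, panel, config.effects, config.seed,
                inject=True, censor_lod=False,
            )
            cdir = os.path.join(outdir, "cohorts")
            write_consortium(cohorts, config.cohort_specs, config.seed, cdir)
            log("simulate", f"simulated {len(cohorts)} cohorts (seed={config.seed})")
        _write_tsv(table_one(cohorts), os.path.join(outdir, "table1.tsv"))

    with _stage("qc"):
        qcdir = os.path.join(outdir, "qc")
        os.makedirs(qcdir, exist_ok=True)
        matrices = {}
        for i, table in enumerate(cohorts):
            reps = generate_replicates(panel, config.n_replicates, replicate_seed(config.seed, i))
            am, report = build_analysis_matrix(table, panel.lod.to_dict(), reps)
            matrices[table.name] = am
            write_qc_report(report, os.path.join(qcdir, f"{table.name}_qc.tsv"))
            log("qc", f"{table.name}: kept {len(am.metabolites)}/{len(table.metabolites)} metabolites")

    with _stage("correlate"):
        pcdir = os.path.join(outdir, "percohort")
        os.makedirs(pcdir, exist_ok=True)
        percohort: dict[str, pd.DataFrame] = {}
        for model_id in config.models:
            frames = []
            for name, am in matrices.items():
                if model_id == "model2" and not am.has_bmi:
                    log("correlate", f"{name}: skipped for model2 (no BMI)")
                    continue
                res = analyze_cohort(am, MODELS[model_id],
                                     family_mode=config.family_mode(name), seed=config.seed)
                frames.append(res)
                _write_tsv(res, os.path.join(pcdir, f"{name}_{model_id}.tsv"))
            percohort[model_id] = pd.concat(frames, ignore_index=True)
            log("correlate", f"{model_id}: {len(percohort[model_id])} cohort-metabolite estimates")

    with _stage("veff"):
        vdir = os.path.join(outdir, "veff")
        os.makedirs(vdir, exist_ok=True)
        refs = [c for c in config.veff_reference if c in matrices] or [next(iter(matrices))]
        reports = {}
        for ref in refs:
            am = matrices[ref]
            corr = am.data[am.metabolites].corr()
            reports[ref] = veff_li(corr, alpha=config.alpha)
        vrows = [
            {"cohort": ref, "m": rep.m, "veff_raw": rep.veff_raw, "veff_int": rep.veff_int,
             "alpha": rep.alpha, "threshold": rep.threshold}
            for ref, rep in reports.items()
        ]
        _write_tsv(pd.DataFrame(vrows), os.path.join(vdir, "veff.tsv"))
        threshold = reports[refs[0]].threshold
        log("veff", f"reference={refs[0]} veff_int={reports[refs[0]].veff_int} "
                    f"threshold={threshold:.4g}")

    with _stage("meta"):
        mdir = os.path.join(outdir, "meta")
        os.makedirs(mdir, exist_ok=True)
        meta_by_model = {}
        for model_id, pc in percohort.items():
            pooled = meta_all(pc, config.cohort_order)
            pooled["fdr"] = bh_adjust(pooled["p"].to_numpy())
            pooled = flag_significant(pooled, threshold)
            meta_by_model[model_id] = pooled
            _write_tsv(pooled, os.path.join(mdir, f"{model_id}.tsv"))
            log("meta", f"{model_id}: {int(pooled['significant'].sum())} significant "
                        f"of {len(pooled)} metabolites at p<{threshold:.4g}")

    with _stage("sensitivity"):
        sdir = os.path.join(outdir, "sensitivity")
        os.makedirs(sdir, exist_ok=True)
        for excl in config.sensitivity_exclude:
            excl = [c for c in excl if c in matrices]
            if not excl:
                continue
            for model_id, pc in percohort.items():
                if not set(pc["cohort"]) - set(excl):
                    continue
                sub = sensitivity_excluding(pc, excl, config.cohort_order, threshold=threshold)
                tag = "_".join(excl)
                _write_tsv(sub, os.path.join(sdir, f"{model_id}_excl_{tag}.tsv"))
                log("sensitivity", f"{model_id} minus {excl}: "
                                   f"{int((sub['p'] < threshold).sum())} significant")

    with _stage("report"):
        if "model1" in meta_by_model and "model2" in meta_by_model:
            table2 = make_table2(meta_by_model, threshold)
            _write_tsv(table2, os.path.join(outdir, "table2.tsv"))
            log("report", f"table2.tsv: {len(table2)} rows")

    significant = list(
        meta_by_model.get("model1", next(iter(meta_by_model.values())))
        .query("significant")["metabolite"]
    )

    if config.make_figures:
        with _stage("figures"):
            fdir = os.path.join(outdir, "figures")
            os.makedirs(fdir, exist_ok=True)
            if "model1" in meta_by_model and "model2" in meta_by_model:
                m1 = meta_by_model["model1"].set_index("metabolite")
                m2 = meta_by_model["model2"].set_index("metabolite")
                common = sorted(set(m1.index) & set(m2.index))
                if len(common) >= 2:
                    profiles = pd.DataFrame(
                        {"r_m1": m1.loc[common, "r"], "r_m2": m2.loc[common, "r"]}
                    )
                    stars = pd.DataFrame(
                        {"r_m1": m1.loc[common, "p"].map(significance_stars),
                         "r_m2": m2.loc[common, "p"].map(significance_stars)}
                    )
                    hc = hclust_order(profiles)
                    render_heatmap(profiles, stars, hc,
                                   os.path.join(fdir, "heatmap.png"),
                                   os.path.join(fdir, "heatmap_order.tsv"))
                    log("figures", f"heat map over {len(common)} metabolites")
            ref = refs[0]
            am = matrices[ref]
            corr_mets = [m for m in significant if m in am.metabolites]
            if len(corr_mets) >= 2:
                rdf, pdf_ = correlogram(am.data[am.metabolites], corr_mets)
                render_correlogram(rdf, pdf_,
                                   os.path.join(fdir, "correlogram.png"),
                                   os.path.join(fdir, "correlogram.tsv"))
                log("figures", f"correlogram of {len(corr_mets)} significant metabolites in {ref}")
            else:
                log("figures", "correlogram skipped (<2 significant metabolites)")

    if config.run_pathway:
        with _stage("pathway"):
            pdir = os.path.join(outdir, "pathway")
            os.makedirs(pdir, exist_ok=True)
            net = default_network()
            syn = default_synonyms()
            results, unmapped = pairwise_search(net, significant, synonyms=syn)
            rows = [
                {"metabolite_a": r.query_source, "metabolite_b": r.query_target,
                 "node_a": r.source, "node_b": r.target, "found": int(r.found),
                 "steps": r.steps, "path": ">".join(r.path)}
                for r in results
            ]
            _write_tsv(
                pd.DataFrame(
                    rows,
                    columns=["metabolite_a", "metabolite_b", "node_a", "node_b",
                             "found", "steps", "path"],
                ),
                os.path.join(pdir, "pairs.tsv"),
            )
            if unmapped:
                with open(os.path.join(pdir, "unmapped.txt"), "w") as fh:
                    fh.write("\n".join(unmapped) + "\n")
            log("pathway", f"{sum(r.found for r in results)} of {len(results)} pairs connected; "
                           f"{len(unmapped)} unmapped")

    with _stage("manifest"):
        canonical = config.canonical_yaml()
        manifest = {
            "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
            "seed": int(config.seed),
            "telometa_version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        with open(os.path.join(outdir, "run.log"), "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    return outdir
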