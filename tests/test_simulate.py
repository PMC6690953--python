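import math

import numpy as np
import pandas as pd
import pytest

from telometa.simulate import (
    CohortSpec,
    PanelSpec,
    TrueEffects,
    consortium_seeds,
    default_cohort_specs,
    default_panel,
    generate_cohort,
    generate_consortium,
    generate_replicates,
    inject_missing_and_lod,
    read_cohort_tsv,
    write_cohort_tsv,
)
from telometa.qc import apply_qc


def _null_effects():
    return TrueEffects(planted_r={}, ltl_loadings={}, met_loadings={})


def test_default_conditions_match_published_design():
    specs = default_cohort_specs()
    assert [s.name for s in specs] == ["KORA", "NTR", "EGCUT", "TwinsUK", "ERF", "LLS", "QIMR"]
    assert sum(s.n for s in specs) == 7853
    assert len(default_panel().metabolite_names) == 131
    assert specs[-1].bmi_mean is None  # QIMR has no BMI


def test_seeded_determinism(small_specs, tiny_panel, planted_effects):
    a = generate_cohort(small_specs[0], tiny_panel, planted_effects, seed=123)
    b = generate_cohort(small_specs[0], tiny_panel, planted_effects, seed=123)
    pd.testing.assert_frame_equal(a.data, b.data)
    c = generate_cohort(small_specs[0], tiny_panel, planted_effects, seed=124)
    assert not c.data["ltl"].equals(a.data["ltl"])


@pytest.mark.parametrize(
    "field,kwargs",
    [
        ("n", dict(n=0)),
        ("pct_female", dict(pct_female=150.0)),
        ("ltl_sd", dict(ltl_sd=0.0)),
        ("family_icc", dict(family_icc=1.0)),
        ("family_size_dist", dict(family_size_dist={1: 0.5, 2: 0.2})),
    ],
)
def test_invalid_spec_raises_naming_field(field, kwargs):
    base = dict(name="X", n=50, pct_female=50.0, ltl_mean=1.8, ltl_sd=0.3,
                age_mean=50.0, age_sd=10.0)
    base.update(kwargs)
    with pytest.raises(ValueError, match=field):
        CohortSpec(**base).validate()


def test_ltl_moments_match_spec():
    # full published KORA size: sample mean within 3 SE, SD within 5%
    spec = default_cohort_specs()[0]
    panel = default_panel()
    t = generate_cohort(spec, panel, _null_effects(), seed=2024)
    se = spec.ltl_sd / math.sqrt(spec.n)
    assert abs(t.data["ltl"].mean() - spec.ltl_mean) < 3 * se
    assert abs(t.data["ltl"].std(ddof=1) - spec.ltl_sd) / spec.ltl_sd < 0.05


def test_family_sizes_partition_sample(small_specs, tiny_panel, planted_effects):
    t = generate_cohort(small_specs[1], tiny_panel, planted_effects, seed=5)
    sizes = t.data.groupby("family_id").size()
    assert sizes.sum() == small_specs[1].n
    assert sizes.max() <= 3


def test_within_block_correlation_recovers_rho():
    mets = [f"M{i}" for i in range(6)]
    panel = PanelSpec(metabolite_names=mets, blocks={"B": mets}, rho_block=0.5,
                      log_mean=3.0, log_sd=0.3, lod=0.0, missing_rate=0.0)
    spec = CohortSpec("BIG", 6000, 50.0, 1.8, 0.3, 50.0, 10.0)
    t = generate_cohort(spec, panel, _null_effects(), seed=9)
    corr = np.log(t.concentrations()).corr().to_numpy()
    off = corr[np.triu_indices(6, k=1)]
    assert np.all(np.abs(off - 0.5) < 0.05)


def test_planted_correlation_recovered_single_cohort(tiny_panel):
    effects = TrueEffects(planted_r={"Met": 0.3}, ltl_loadings={}, met_loadings={})
    spec = CohortSpec("BIG", 8000, 50.0, 1.8, 0.3, 50.0, 10.0)
    t = generate_cohort(spec, tiny_panel, effects, seed=17)
    r = np.corrcoef(t.data["ltl"], np.log(t.data["Met"]))[0, 1]
    assert abs(r - 0.3) < 0.04


def test_consortium_seed_scheme_is_prefix_stable(small_specs, tiny_panel, planted_effects):
    assert consortium_seeds(5, 3) == consortium_seeds(5, 4)[:3]
    three = generate_consortium(small_specs, tiny_panel, planted_effects, seed=5)
    extra = small_specs + [CohortSpec("DELTA", 40, 50.0, 1.8, 0.3, 50.0, 10.0)]
    four = generate_consortium(extra, tiny_panel, planted_effects, seed=5)
    for a, b in zip(three, four):
        pd.testing.assert_frame_equal(a.data, b.data)
    assert sum(t.n for t in three) == sum(s.n for s in small_specs)


def test_duplicate_cohort_names_rejected(small_specs, tiny_panel, planted_effects):
    with pytest.raises(ValueError, match="duplicate"):
        generate_consortium([small_specs[0], small_specs[0]], tiny_panel, planted_effects, seed=1)


def test_single_cohort_consortium(small_specs, tiny_panel, planted_effects):
    (one,) = generate_consortium(small_specs[:1], tiny_panel, planted_effects, seed=3)
    assert one.n == small_specs[0].n


def test_bmi_absent_cohort_has_no_bmi_column(small_consortium):
    gamma = small_consortium[2]
    assert "bmi" not in gamma.data.columns


def test_n_bmi_masks_expected_count(tiny_panel, planted_effects):
    spec = CohortSpec("X", 100, 50.0, 1.8, 0.3, 50.0, 10.0, 26.0, 4.0, n_bmi=80)
    t = generate_cohort(spec, tiny_panel, planted_effects, seed=1)
    assert t.data["bmi"].notna().sum() == 80


def test_inject_noop_when_rates_zero(small_consortium, tiny_panel):
    table = small_consortium[0]
    panel = PanelSpec(metabolite_names=tiny_panel.metabolite_names, blocks=tiny_panel.blocks,
                      rho_block=dict(tiny_panel.rho_block), log_mean=tiny_panel.log_mean,
                      log_sd=tiny_panel.log_sd, lod=0.0, missing_rate=0.0)
    out, report = inject_missing_and_lod(table, panel, seed=1)
    pd.testing.assert_frame_equal(out.data, table.data)
    assert (report[["n_missing", "n_below_lod"]].to_numpy() == 0).all()


def test_injected_missingness_trips_qc_rule(tiny_panel, tiny_replicates):
    # 6% MCAR on one metabolite at n=3002 fails the <5% rule w.h.p.
    spec = CohortSpec("BIG", 3002, 50.0, 1.8, 0.3, 50.0, 10.0)
    panel = PanelSpec(metabolite_names=tiny_panel.metabolite_names, blocks=tiny_panel.blocks,
                      rho_block=dict(tiny_panel.rho_block), log_mean=tiny_panel.log_mean,
                      log_sd=tiny_panel.log_sd, lod=0.0,
                      missing_rate={m: (0.06 if m == "Met" else 0.0)
                                    for m in tiny_panel.metabolite_names})
    t = generate_cohort(spec, panel, _null_effects(), seed=21)
    t, _ = inject_missing_and_lod(t, panel, seed=22)
    _, report = apply_qc(t, panel.lod.to_dict(), tiny_replicates)
    row = report.set_index("metabolite").loc["Met"]
    assert row["verdict"] == "excluded"
    assert "missingness" in row["reasons"]


def test_lod_above_upper_percentile_fails_median_rule(tiny_panel, tiny_replicates):
    # an LOD above the 60th percentile of reported values puts the median
    # below it, so the metabolite is excluded by the median-above-LOD rule
    spec = CohortSpec("X", 500, 50.0, 1.8, 0.3, 50.0, 10.0)
    t = generate_cohort(spec, tiny_panel, _null_effects(), seed=30)
    lods = tiny_panel.lod.to_dict()
    lods["Tyr"] = float(t.data["Tyr"].quantile(0.60))
    _, report = apply_qc(t, lods, tiny_replicates)
    row = report.set_index("metabolite").loc["Tyr"]
    assert row["verdict"] == "excluded"
    assert "LOD" in row["reasons"]


def test_censoring_convention_sets_below_lod_missing(tiny_panel):
    spec = CohortSpec("X", 300, 50.0, 1.8, 0.3, 50.0, 10.0)
    t = generate_cohort(spec, tiny_panel, _null_effects(), seed=40)
    lods = tiny_panel.lod.to_dict()
    lods["Met"] = float(t.data["Met"].quantile(0.10))  # censor the bottom decile
    panel = PanelSpec(metabolite_names=tiny_panel.metabolite_names, blocks=tiny_panel.blocks,
                      rho_block=dict(tiny_panel.rho_block), log_mean=tiny_panel.log_mean,
                      log_sd=tiny_panel.log_sd, lod=lods, missing_rate=0.0)
    t2, report = inject_missing_and_lod(t, panel, seed=41)
    rep = report.set_index("metabolite")
    n_below = int((t.data["Met"] < lods["Met"]).sum())
    assert rep.loc["Met", "n_below_lod"] == n_below
    assert t2.data["Met"].isna().sum() == n_below
    # MCAR-only variant leaves the values in place for the QC stage
    t3, _ = inject_missing_and_lod(t, panel, seed=41, censor_lod=False)
    assert t3.data["Met"].isna().sum() == 0


def test_replicate_cv_matches_truth(tiny_panel):
    reps = generate_replicates(tiny_panel, n_replicates=60, seed=4)
    cv = reps["Met"].std(ddof=1) / reps["Met"].mean()
    assert abs(cv - 0.08) < 0.03


def test_tsv_roundtrip(tmp_path, small_consortium):
    table = small_consortium[1]
    path = tmp_path / "BETA.tsv"
    write_cohort_tsv(table, path)
    back = read_cohort_tsv(path, name="BETA")
    assert back.metabolites == table.metabolites
    pd.testing.assert_frame_equal(back.data, table.data, check_dtype=False)
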