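import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from oracles import partial_corr_inverse_matrix
from telometa.experiments import cluster_type1_experiment
from telometa.partialcorr import (
    MODEL1,
    MODEL2,
    analyze_cohort,
    partial_corr,
    partial_corr_family,
    reml_random_intercept,
    residualize,
)
from telometa.qc import build_analysis_matrix


def test_residualize_intercept_is_centering():
    out = residualize([1.0, 2.0, 3.0], np.ones((3, 1)))
    assert out == pytest.approx([-1.0, 0.0, 1.0])


def test_residualize_exact_fit_gives_zero():
    x = np.arange(5, dtype=float)
    X = np.column_stack([np.ones(5), x])
    out = residualize(2.0 + 3.0 * x, X)
    assert np.abs(out).max() < 1e-12


def test_residualize_worked_example():
    # y = [1,2,2,4] on intercept + [0,1,2,3]: slope 0.9, intercept 0.9
    X = np.column_stack([np.ones(4), [0.0, 1.0, 2.0, 3.0]])
    out = residualize([1.0, 2.0, 2.0, 4.0], X)
    assert out == pytest.approx([0.1, 0.2, -0.7, 0.4], abs=1e-12)


def test_residualize_orthogonality_random():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(10, 60))
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        y = rng.standard_normal(n)
        r = residualize(y, X)
        assert np.abs(X.T @ r).max() < 1e-8 * max(1.0, np.linalg.norm(y))


def test_residualize_prunes_collinear_columns():
    n = 20
    x = np.linspace(0, 1, n)
    X = np.column_stack([np.ones(n), x, 2 * x])  # third column collinear
    out = residualize(np.sin(x), X)
    assert np.abs(np.column_stack([np.ones(n), x]).T @ out).max() < 1e-10


def test_partial_corr_no_covariates_is_pearson():
    rng = np.random.default_rng(1)
    x, y = rng.standard_normal(50), rng.standard_normal(50)
    r, df, p = partial_corr(x, y, np.ones((50, 1)))
    ref_r, ref_p = stats.pearsonr(x, y)
    assert r == pytest.approx(ref_r, abs=1e-12)
    assert df == 48
    assert p == pytest.approx(ref_p, rel=1e-10)


def test_partial_corr_perfect_correlation_p_floor():
    x = np.linspace(0, 1, 30)
    r, _, p = partial_corr(x, x, np.ones((30, 1)))
    assert r == pytest.approx(1.0)
    assert 0.0 < p <= np.finfo(float).tiny


def test_partial_corr_matches_inverse_matrix_oracle():
    rng = np.random.default_rng(2)
    for _ in range(50):
        n = int(rng.integers(15, 80))
        kz = int(rng.integers(1, 4))
        Z = rng.standard_normal((n, kz))
        x = rng.standard_normal(n) + Z @ rng.standard_normal(kz)
        y = rng.standard_normal(n) + Z @ rng.standard_normal(kz)
        r, _, _ = partial_corr(x, y, np.column_stack([np.ones(n), Z]))
        assert r == pytest.approx(partial_corr_inverse_matrix(x, y, Z), abs=1e-10)


def test_partial_corr_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    n = 80
    df = pd.DataFrame({"x": rng.standard_normal(n), "y": rng.standard_normal(n),
                       "a": rng.standard_normal(n), "b": rng.standard_normal(n)})
    ref = pg.partial_corr(df, x="x", y="y", covar=["a", "b"])
    r, _, p = partial_corr(df["x"], df["y"], np.column_stack([np.ones(n), df["a"], df["b"]]))
    assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-8)


@given(
    ax=st.floats(0.1, 5.0), bx=st.floats(-3.0, 3.0),
    ay=st.floats(0.1, 5.0), by=st.floats(-3.0, 3.0),
)
def test_partial_corr_affine_invariance(ax, bx, ay, by):
    rng = np.random.default_rng(4)
    n = 40
    Z = rng.standard_normal((n, 2))
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), Z])
    r0, _, p0 = partial_corr(x, y, X)
    r1, _, p1 = partial_corr(ax * x + bx, ay * y + by, X)
    assert r1 == pytest.approx(r0, abs=1e-9)
    assert p1 == pytest.approx(p0, rel=1e-6)


def test_partial_corr_sign_flip():
    rng = np.random.default_rng(5)
    n = 60
    Z = rng.standard_normal((n, 2))
    x, y = rng.standard_normal(n), rng.standard_normal(n)
    X = np.column_stack([np.ones(n), Z])
    r0, _, p0 = partial_corr(x, y, X)
    r1, _, p1 = partial_corr(-x, y, X)
    assert r1 == pytest.approx(-r0, abs=1e-12)
    assert p1 == pytest.approx(p0, rel=1e-12)


def test_partial_corr_insufficient_rows():
    with pytest.raises(ValueError, match="insufficient"):
        partial_corr([1.0, 2.0], [2.0, 1.0], np.ones((2, 1)))


def test_reml_matches_statsmodels_mixedlm():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(6)
    nfam, size = 120, 3
    n = nfam * size
    fam = np.repeat(np.arange(nfam), size)
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = X @ np.array([0.5, -1.0]) + 0.7 * rng.standard_normal(nfam)[fam] + rng.standard_normal(n)
    _, lam, beta = reml_random_intercept(y, X, fam)
    fit = sm.MixedLM(y, X, groups=fam).fit(reml=True)
    assert lam == pytest.approx(float(np.asarray(fit.cov_re)[0, 0]) / fit.scale, rel=1e-3)
    assert beta == pytest.approx(fit.fe_params, abs=1e-6)


def test_family_modes_agree_on_singletons():
    rng = np.random.default_rng(7)
    n = 100
    Z = rng.standard_normal((n, 2))
    x, y = rng.standard_normal(n), rng.standard_normal(n)
    X = np.column_stack([np.ones(n), Z])
    fam = np.arange(n)  # all singleton families
    r_none, _, _, p_none = partial_corr_family(x, y, X, fam, mode="none")
    r_mix, _, _, p_mix = partial_corr_family(x, y, X, fam, mode="mixed_residual")
    r_one, _, _, p_one = partial_corr_family(x, y, X, fam, mode="one_per_family", seed=1)
    assert r_mix == pytest.approx(r_none, abs=1e-8)
    assert r_one == pytest.approx(r_none, abs=1e-12)
    assert p_mix == pytest.approx(p_none, rel=1e-6)


def test_one_per_family_seeded_determinism():
    rng = np.random.default_rng(8)
    n = 120
    fam = np.repeat(np.arange(40), 3)
    x, y = rng.standard_normal(n), rng.standard_normal(n)
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    a = partial_corr_family(x, y, X, fam, mode="one_per_family", seed=42)
    b = partial_corr_family(x, y, X, fam, mode="one_per_family", seed=42)
    assert a == b
    assert a[1] == 40  # one row per family


def test_family_clustering_inflates_naive_test_but_not_mixed():
    """Planted icc=0.5, null association, 200 families of 4: the naive t test
    is anticonservative while the random-intercept residualization keeps the
    type-I error near nominal."""
    res = cluster_type1_experiment(n_replicates=500, seed=2)
    assert res["type1_mixed"] <= 0.08
    assert res["type1_none"] > 0.08


def test_analyze_cohort_available_case_counts(small_consortium, tiny_panel, tiny_replicates):
    table = small_consortium[0]
    # knock out some Met values to force a different available-case n
    data = table.data.copy()
    data.loc[data.index[:10], "Met"] = np.nan
    from telometa.simulate import CohortTable

    am, _ = build_analysis_matrix(CohortTable(table.name, data, table.metabolites),
                                  tiny_panel.lod.to_dict(), tiny_replicates)
    res = analyze_cohort(am, MODEL1, family_mode="none").set_index("metabolite")
    assert res.loc["Met", "n"] == table.n - 10
    assert res.loc["Tyr", "n"] == table.n
    assert (res["df"] == res["n"] - 2 - res["k"]).all()


def test_analyze_cohort_model2_requires_bmi(small_consortium, tiny_panel, tiny_replicates):
    gamma = small_consortium[2]  # no BMI
    am, _ = build_analysis_matrix(gamma, tiny_panel.lod.to_dict(), tiny_replicates)
    with pytest.raises(ValueError, match="bmi"):
        analyze_cohort(am, MODEL2)


def test_all_female_cohort_drops_sex_covariate(small_consortium, tiny_panel, tiny_replicates):
    gamma = small_consortium[2]  # 100% female
    am, _ = build_analysis_matrix(gamma, tiny_panel.lod.to_dict(), tiny_replicates)
    res = analyze_cohort(am, MODEL1, family_mode="none")
    assert (res["k"] == 1).all()  # sex is constant, pruned from the design
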