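"""Differential screening: rank tests, effect scores, covariate-adjusted OLS, BH."""

import numpy as np
import pandas as pd
import pytest

from mucohub.differential import (
    bh_adjust,
    covariate_adjusted_association,
    differential_features,
    effect_score,
    mann_whitney,
)
from mucohub.tabio import AbundanceTable, StudyMetadata


def test_mann_whitney_exact_separated():
    u, p = mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2/20 rank splits are as extreme


def test_mann_whitney_identical_and_tied_groups():
    _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0)
    _, p_tied = mann_whitney([1, 2], [1, 2])
    assert p_tied == pytest.approx(1.0)


def test_mann_whitney_monotone_transform_invariance():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
    _, p1 = mann_whitney(a, b)
    _, p2 = mann_whitney(np.exp(a), np.exp(b))  # strictly monotone transform
    assert p1 == pytest.approx(p2)


def test_mann_whitney_empty_group_rejected():
    with pytest.raises(ValueError):
        mann_whitney([], [1, 2])


def test_bh_adjust_step_up():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_monotone_in_ranked_p():
    rng = np.random.default_rng(1)
    p = rng.uniform(0, 1, 30)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(q >= p - 1e-12)


def _screen_fixture(mean_a, mean_b, n_per=5, depth=1_000_000):
    """Two-feature table where feature f0 has the requested CPM group means."""
    ids = [f"s{i}" for i in range(2 * n_per)]
    f0 = np.array([mean_a] * n_per + [mean_b] * n_per, dtype=float)
    f1 = depth - f0
    table = AbundanceTable(["f0", "f1"], ids, np.vstack([f0, f1]))
    meta = StudyMetadata(ids, pd.Series(["A"] * n_per + ["B"] * n_per, index=ids))
    return table, meta


def test_effect_score_log10_cpm_difference():
    table, meta = _screen_fixture(10_000, 100)
    res = effect_score(table, meta)
    row = res.table.set_index("feature").loc["f0"]
    assert row["score"] == pytest.approx(np.log10(9901), abs=1e-6)
    assert row["direction"] == "A"
    assert row["p"] < 0.05 and bool(row["flagged"])


def test_effect_score_threshold_is_strict_and_identical_feature_unflagged():
    # score log10(|Δ|+1) = 1.2  ->  below the 1.5 bar, not flagged
    delta = 10**1.2 - 1
    table, meta = _screen_fixture(1000 + delta, 1000)
    res = effect_score(table, meta, threshold=1.5)
    row = res.table.set_index("feature").loc["f0"]
    assert row["score"] == pytest.approx(1.2, abs=1e-6)
    assert not row["flagged"]
    # feature with identical group distributions fails the screen
    table2, meta2 = _screen_fixture(500, 500)
    assert not res.table.empty
    assert not effect_score(table2, meta2).table["flagged"].any()


def test_effect_score_depth_invariance():
    """CPM normalization makes the score invariant to per-sample depth."""
    rng = np.random.default_rng(2)
    ids = [f"s{i}" for i in range(10)]
    base = rng.integers(50, 500, size=(6, 10)).astype(float)
    scaled = base * rng.uniform(0.5, 4.0, size=10)  # per-sample depth distortion
    meta = StudyMetadata(ids, pd.Series(["A"] * 5 + ["B"] * 5, index=ids))
    s1 = effect_score(AbundanceTable([f"f{i}" for i in range(6)], ids, base), meta)
    s2 = effect_score(AbundanceTable([f"f{i}" for i in range(6)], ids, scaled), meta)
    np.testing.assert_allclose(s1.table["score"], s2.table["score"], atol=1e-9)


def test_effect_score_rejects_bad_threshold(small_table, small_metadata):
    with pytest.raises(ValueError):
        effect_score(small_table, small_metadata, threshold=0.0)


def _ols_fixture(y_values, covariate):
    """4-feature table whose f0 log-relative abundance is controlled via y."""
    ids = [f"s{i}" for i in range(len(y_values))]
    n = len(ids)
    f0 = np.exp(np.asarray(y_values, dtype=float)) * 1000
    rest = np.vstack([np.full(n, 800.0), np.full(n, 900.0), np.full(n, 1100.0)])
    table = AbundanceTable(["f0", "f1", "f2", "f3"], ids, np.vstack([f0, rest]))
    meta = StudyMetadata(
        ids,
        pd.Series(["A"] * (n // 2) + ["B"] * (n // 2), index=ids),
        covariates=pd.DataFrame({"bw": covariate}, index=ids),
    )
    return table, meta


def test_covariate_model_matches_statsmodels():
    """Independent oracle: per-feature OLS via statsmodels on the same design."""
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    ids = [f"s{i}" for i in range(12)]
    counts = rng.integers(10, 5000, size=(5, 12)).astype(float)
    bw = rng.normal(25, 2, 12)
    table = AbundanceTable([f"f{i}" for i in range(5)], ids, counts)
    meta = StudyMetadata(
        ids,
        pd.Series(["A"] * 6 + ["B"] * 6, index=ids),
        covariates=pd.DataFrame({"bw": bw}, index=ids),
    )
    ours = covariate_adjusted_association(table, meta, covariate="bw").set_index("feature")
    group = np.array([0.0] * 6 + [1.0] * 6)
    X = sm.add_constant(np.column_stack([group, bw]))
    for i in range(5):
        x = counts[i] / counts.sum(axis=0)
        y = np.log(x + x[x > 0].min() / 2)
        fit = sm.OLS(y, X).fit()
        assert ours.loc[f"f{i}", "coef"] == pytest.approx(fit.params[1], rel=1e-8)
        assert ours.loc[f"f{i}", "coef_p"] == pytest.approx(fit.pvalues[1], rel=1e-6)


def test_covariate_model_degenerate_cases():
    # group effect exactly zero: constant feature -> coef 0, p 1
    table, meta = _ols_fixture([1.0] * 6, [1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    res = covariate_adjusted_association(table, meta, covariate="bw").set_index("feature")
    assert res.loc["f0", "coef"] == pytest.approx(0.0)
    assert res.loc["f0", "coef_p"] == pytest.approx(1.0)
    # constant covariate dropped with a warning
    table2, meta2 = _ols_fixture([0, 0, 0, 1, 1, 1], [5.0] * 6)
    with pytest.warns(UserWarning, match="constant"):
        res2 = covariate_adjusted_association(table2, meta2, covariate="bw")
    assert res2.set_index("feature").loc["f0", "coef_p"] < 1e-6


def test_perfect_group_separation_floors_p():
    """Transformed abundance a deterministic function of the group indicator:
    the group coefficient reproduces the exact two-point contrast and the
    residual variance vanishes, flooring p."""
    table, meta = _ols_fixture([0, 0, 0, 1, 1, 1], [1.0, -1.0, 0.0, -1.0, 1.0, 0.0])
    res = covariate_adjusted_association(table, meta, covariate="bw").set_index("feature")
    # expected contrast on the log(TSS + pseudocount) scale, computed directly
    rel = table.counts[0] / table.counts.sum(axis=0)
    y = np.log(rel + rel[rel > 0].min() / 2)
    expected = y[3:].mean() - y[:3].mean()
    assert res.loc["f0", "coef"] == pytest.approx(expected, abs=1e-9)
    assert res.loc["f0", "coef_p"] <= 1e-12


def test_null_screen_flag_rate_bounded_by_rank_test_rate():
    rng = np.random.default_rng(4)
    ids = [f"s{i}" for i in range(20)]
    counts = rng.integers(1, 2000, size=(300, 20)).astype(float)
    table = AbundanceTable([f"f{i}" for i in range(300)], ids, counts)
    meta = StudyMetadata(ids, pd.Series(["A"] * 10 + ["B"] * 10, index=ids))
    res = effect_score(table, meta)
    n_flagged = int(res.table["flagged"].sum())
    n_rank = int((res.table["p"] < 0.05).sum())
    assert n_flagged <= n_rank


def test_differential_features_joins_models(small_table, small_metadata):
    res = differential_features(small_table, small_metadata, covariate="body_weight")
    assert {"p", "q", "score", "coef", "coef_p", "coef_q"} <= set(res.table.columns)
    assert len(res.table) == small_table.n_features
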