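"""Permutation test, BH adjustment, ANOVA/Tukey contrast patterns."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirserum import (
    DataError,
    MetadataError,
    SizeError,
    anova_tukey_classify,
    bh_adjust,
    exhaustive_permutation_test,
    permutation_test,
    simulate_cohort,
    SyntheticConfig,
)
from mirserum.differential import classify_pattern

from conftest import bh_oracle, exhaustive_p_oracle, make_metadata, make_norm


def _two_group(values_row, n_disease):
    n = len(values_row)
    norm = make_norm(pd.DataFrame([values_row], index=["m0"], columns=[f"S{i}" for i in range(n)]))
    meta = make_metadata(["OSCC"] * n_disease + ["CONTROL"] * (n - n_disease), ids=list(norm.values.columns))
    return norm, meta


def test_exhaustive_worked_example_two_vs_two():
    # values {1,2} vs {3,4}: only the two extreme splits reach |T| = 2,
    # so the exact two-sided p is 2/6 = 1/3
    norm, meta = _two_group([1.0, 2.0, 3.0, 4.0], 2)
    res = exhaustive_permutation_test(norm, meta, min_detection=0.0)
    assert res.loc["m0", "p_raw"] == pytest.approx(1 / 3)
    assert res.loc["m0", "statistic"] == pytest.approx(-2.0)
    assert res.loc["m0", "direction"] == "UP"


def test_exhaustive_identical_groups_give_p_one():
    norm, meta = _two_group([5.0, 7.0, 5.0, 7.0], 2)
    res = exhaustive_permutation_test(norm, meta, min_detection=0.0)
    assert res.loc["m0", "p_raw"] == 1.0


def test_exhaustive_matches_naive_enumeration_with_missing_cells():
    rng = np.random.default_rng(0)
    vals = rng.normal(0, 1, (6, 8))
    vals[rng.random(vals.shape) < 0.15] = np.nan
    frame = pd.DataFrame(vals, index=[f"m{i}" for i in range(6)], columns=[f"S{i}" for i in range(8)])
    frame = frame.dropna(how="all")
    norm = make_norm(frame)
    is_dis = np.array([True] * 4 + [False] * 4)
    meta = make_metadata(["CIS"] * 4 + ["CONTROL"] * 4, ids=list(frame.columns))
    res = exhaustive_permutation_test(norm, meta, min_detection=0.0)
    expected = exhaustive_p_oracle(frame.loc[res.index].to_numpy(), is_dis)
    assert np.allclose(res["p_raw"].to_numpy(), expected)


def test_exhaustive_guard_rejects_large_cohorts():
    rng = np.random.default_rng(1)
    n = 24
    norm = make_norm(pd.DataFrame([rng.normal(size=n)], index=["m0"], columns=[f"S{i}" for i in range(n)]))
    meta = make_metadata(["OSCC"] * 12 + ["CONTROL"] * 12, ids=list(norm.values.columns))
    with pytest.raises(SizeError):
        exhaustive_permutation_test(norm, meta, min_detection=0.0)


def test_monte_carlo_agrees_with_exhaustive_within_binomial_error():
    rng = np.random.default_rng(3)
    frame = pd.DataFrame(
        rng.normal(0, 1, (8, 10)) + np.linspace(0, 1.5, 8)[:, None] * ([1] * 5 + [0] * 5),
        index=[f"m{i}" for i in range(8)],
        columns=[f"S{i}" for i in range(10)],
    )
    norm = make_norm(frame)
    meta = make_metadata(["OSCC"] * 5 + ["CONTROL"] * 5, ids=list(frame.columns))
    exact = exhaustive_permutation_test(norm, meta, min_detection=0.0)
    n_perm = 10_000
    mc = permutation_test(norm, meta, n_permutations=n_perm, seed=5, min_detection=0.0)
    for m in exact.index:
        p = exact.loc[m, "p_raw"]
        tol = 3 * np.sqrt(p * (1 - p) / n_perm) + 1.5 / (n_perm + 1)
        assert abs(mc.loc[m, "p_raw"] - p) <= tol


def test_detection_gate_excludes_below_sixty_percent():
    # m_low detected in 59% of 100 samples -> excluded; m_gate at exactly
    # 60% -> included (inclusive boundary)
    n = 100
    rng = np.random.default_rng(4)
    base = rng.normal(0, 1, (2, n))
    base[0, 59:] = np.nan  # 59 detected
    base[1, 60:] = np.nan  # 60 detected
    frame = pd.DataFrame(base, index=["m_low", "m_gate"], columns=[f"S{i}" for i in range(n)])
    norm = make_norm(frame)
    meta = make_metadata(["OSCC"] * 50 + ["CONTROL"] * 50, ids=list(frame.columns))
    res = permutation_test(norm, meta, n_permutations=50, seed=0)
    assert "m_low" not in res.index
    assert "m_gate" in res.index


def test_p_floor_and_direction_consistency():
    cfg = SyntheticConfig(
        n_mirnas=20, n_disease=10, n_control=10, spiked_up=((0, 3.0),), spiked_down=((1, 3.0),), seed=6
    )
    from mirserum import global_mean_normalize

    matrix, meta, _, _ = simulate_cohort(cfg)
    res = permutation_test(global_mean_normalize(matrix), meta, n_permutations=999, seed=1)
    assert (res["p_raw"] >= 1 / 1000).all()
    assert (res["p_adj"] >= res["p_raw"] - 1e-15).all()
    assert res.loc[res["statistic"] < 0, "direction"].eq("UP").all()
    assert res.loc[res["statistic"] >= 0, "direction"].eq("DOWN").all()
    assert res.loc["mir-000", "direction"] == "UP"
    assert res.loc["mir-001", "direction"] == "DOWN"


def test_bh_adjust_matches_brute_force_oracle():
    cases = [
        [0.01, 0.02, 0.03, 0.04],  # step-up collapses all to 0.04
        [0.5],
        [0.001, 0.5, 0.9, 0.04, 0.04],
    ]
    for p in cases:
        assert bh_adjust(p) == pytest.approx(bh_oracle(p))
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30))
def test_bh_adjust_properties(p):
    adj = bh_adjust(p)
    assert np.all(adj <= 1.0 + 1e-12)
    assert np.all(adj >= np.asarray(p) - 1e-12)
    # order of distinct raw p-values is preserved
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)
    assert adj == pytest.approx(bh_oracle(p))


def test_bh_adjust_rejects_out_of_range():
    with pytest.raises(DataError):
        bh_adjust([0.0, 0.5])
    with pytest.raises(DataError):
        bh_adjust([1.5])


def test_exchangeability_exhaustive_p_invariant_to_sample_order():
    rng = np.random.default_rng(7)
    frame = pd.DataFrame(
        rng.normal(0, 1, (4, 8)), index=[f"m{i}" for i in range(4)], columns=[f"S{i}" for i in range(8)]
    )
    groups = ["OSCC"] * 3 + ["CONTROL"] * 5
    norm = make_norm(frame)
    meta = make_metadata(groups, ids=list(frame.columns))
    res1 = exhaustive_permutation_test(norm, meta, min_detection=0.0)
    perm = rng.permutation(8)
    frame2 = frame.iloc[:, perm]
    meta2 = meta.iloc[perm]
    res2 = exhaustive_permutation_test(make_norm(frame2), meta2, min_detection=0.0)
    assert np.allclose(res1["p_raw"].to_numpy(), res2["p_raw"].to_numpy())


def test_requires_both_groups():
    norm, _ = _two_group([1.0, 2.0, 3.0], 0)
    meta = make_metadata(["CONTROL"] * 3, ids=list(norm.values.columns))
    with pytest.raises(MetadataError):
        permutation_test(norm, meta, n_permutations=10, seed=0)


@pytest.mark.parametrize(
    "flags, label",
    [
        ((True, False, False), "CIS_SPECIFIC"),
        ((True, False, True), "CIS_VS_BOTH"),
        ((True, True, False), "SHARED"),
        ((False, True, False), "OSCC_SPECIFIC"),
        ((False, False, False), "NONE"),
        ((False, False, True), "NONE"),
        ((True, True, True), "NONE"),
    ],
)
def test_pattern_label_is_pure_function_of_flags(flags, label):
    assert classify_pattern(*flags) == label


def _three_group_norm(shift_cis=0.0, shift_oscc=0.0, seed=0, n_per=8, n_mirnas=6):
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 0.5, (n_mirnas, 3 * n_per))
    vals[0, :n_per] += shift_cis
    vals[0, n_per : 2 * n_per] += shift_oscc
    frame = pd.DataFrame(
        vals, index=[f"m{i}" for i in range(n_mirnas)], columns=[f"S{i}" for i in range(3 * n_per)]
    )
    meta = make_metadata(
        ["CIS"] * n_per + ["OSCC"] * n_per + ["CONTROL"] * n_per, ids=list(frame.columns)
    )
    return make_norm(frame), meta


def test_anova_recovers_contrast_patterns():
    # a large CIS-only shift separates CIS from BOTH other groups
    norm, meta = _three_group_norm(shift_cis=3.0, seed=1)
    res = anova_tukey_classify(norm, meta, min_detection=0.0)
    assert res.loc["m0", "pattern"] == "CIS_VS_BOTH"

    # equal shifts in both disease groups: shared disease signature
    norm, meta = _three_group_norm(shift_cis=3.0, shift_oscc=3.0, seed=2)
    res = anova_tukey_classify(norm, meta, min_detection=0.0)
    assert res.loc["m0", "pattern"] == "SHARED"

    # CIS-specific requires OSCC to sit between CIS and control, close
    # enough to both that neither of its contrasts clears Tukey's HSD
    norm, meta = _three_group_norm(shift_cis=0.95, shift_oscc=0.475, seed=2, n_per=10)
    res = anova_tukey_classify(norm, meta, min_detection=0.0)
    assert res.loc["m0", "pattern"] == "CIS_SPECIFIC"


def test_anova_null_is_mostly_none_after_bh():
    norm, meta = _three_group_norm(seed=3, n_mirnas=40)
    res = anova_tukey_classify(norm, meta, min_detection=0.0)
    assert (res["pattern"] == "NONE").mean() == 1.0


def test_anova_small_group_labeled_none_with_warning():
    norm, meta = _three_group_norm(shift_cis=3.0, seed=4)
    vals = norm.values.copy()
    vals.loc["m1", meta.index[meta["group"] == "CIS"][1:]] = np.nan  # one CIS value left
    with pytest.warns(UserWarning, match="NONE"):
        res = anova_tukey_classify(make_norm(vals), meta, min_detection=0.0)
    assert res.loc["m1", "pattern"] == "NONE"
    assert np.isnan(res.loc["m1", "p_anova"])
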