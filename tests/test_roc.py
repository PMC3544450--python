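"""ROC/AUC, operating points, bootstrap CIs and marker ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirserum import (
    DataError,
    bootstrap_auc_ci,
    mann_whitney_auc,
    rank_biomarkers,
    roc_analysis,
    roc_with_ci,
)

from conftest import auc_pair_oracle


def _series(values):
    return pd.Series(values, index=[f"S{i}" for i in range(len(values))], dtype=float)


def test_perfect_separation_auc_one_sens_spec_one():
    scores = _series([3.0, 2.0, 1.0, 0.0])
    res = roc_analysis(scores, [True, True, False, False], orientation="high")
    assert res.auc == pytest.approx(1.0)
    assert res.sensitivity == pytest.approx(1.0)
    assert res.specificity == pytest.approx(1.0)


def test_interleaved_scores_brute_force_example():
    # disease {0.9, 0.4}, control {0.6, 0.1}: 3 of 4 pairs concordant
    res = roc_analysis(
        _series([0.9, 0.4, 0.6, 0.1]), [True, True, False, False], orientation="high"
    )
    assert res.auc == pytest.approx(0.75)
    assert res.auc == pytest.approx(auc_pair_oracle([0.9, 0.4], [0.6, 0.1]))


def test_constant_scores_give_auc_half_with_warning():
    with pytest.warns(UserWarning, match="identical"):
        res = roc_analysis(_series([1.0] * 6), [True] * 3 + [False] * 3, orientation="high")
    assert res.auc == pytest.approx(0.5)


@settings(max_examples=150, derandomize=True)
@given(
    pos=st.lists(st.integers(min_value=-5, max_value=5), min_size=1, max_size=20),
    neg=st.lists(st.integers(min_value=-5, max_value=5), min_size=1, max_size=20),
)
def test_trapezoid_auc_equals_pair_counting_with_ties(pos, neg):
    scores = _series([float(x) for x in pos + neg])
    labels = [True] * len(pos) + [False] * len(neg)
    res = roc_analysis(scores, labels, orientation="high")
    assert res.auc == pytest.approx(auc_pair_oracle(pos, neg))
    assert res.auc == pytest.approx(mann_whitney_auc(np.array(pos, float), np.array(neg, float)))
    # orientation identity under the tie convention
    flipped = mann_whitney_auc(-np.array(pos, float), -np.array(neg, float))
    assert res.auc + flipped == pytest.approx(1.0)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    pos, neg = rng.normal(1, 1, 15), rng.normal(0, 1, 12)
    scores = np.concatenate([pos, neg])
    labels = [True] * 15 + [False] * 12
    a = roc_analysis(_series(scores), labels, orientation="high").auc
    b = roc_analysis(_series(np.exp(scores)), labels, orientation="high").auc
    assert a == pytest.approx(b)


def test_auto_orientation_flips_downregulated_markers():
    # low ΔCp in disease (upregulated marker)
    res_low = roc_analysis(_series([-2.0, -1.5, 0.5, 1.0]), [True, True, False, False])
    assert res_low.low_dcp_is_disease and res_low.auc >= 0.5
    # high ΔCp in disease (downregulated marker)
    res_high = roc_analysis(_series([2.0, 1.5, -0.5, -1.0]), [True, True, False, False])
    assert not res_high.low_dcp_is_disease and res_high.auc >= 0.5


def test_undetected_scores_excluded_with_count():
    scores = _series([np.nan, -1.0, -2.0, 1.0, 2.0])
    res = roc_analysis(scores, [True, True, True, False, False])
    assert res.n_excluded == 1
    assert res.n_disease == 2 and res.n_control == 2


def test_youden_ties_break_toward_higher_specificity():
    # two thresholds reach J = 0.5; the chosen one has the lower FPR
    scores = _series([4.0, 3.0, 1.0, 2.5, 2.0, 0.5])
    labels = [True, True, True, False, False, False]
    res = roc_analysis(scores, labels, orientation="high")
    assert res.sensitivity + res.specificity - 1 == pytest.approx(
        max(
            tpr - fpr
            for tpr, fpr in zip(res.tpr, res.fpr)
        )
    )
    same_j = [
        (1 - fpr) for tpr, fpr in zip(res.tpr, res.fpr) if (tpr - fpr) == pytest.approx(res.sensitivity + res.specificity - 1)
    ]
    assert res.specificity == pytest.approx(max(same_j))


def test_single_class_is_an_error():
    with pytest.raises(DataError):
        roc_analysis(_series([1.0, 2.0]), [True, True])


def test_bootstrap_ci_deterministic_and_collapses_for_perfect_marker():
    scores = np.array([5.0, 4.0, 3.5, 1.0, 0.5, 0.0])
    labels = np.array([True, True, True, False, False, False])
    ci1 = bootstrap_auc_ci(scores, labels, n_boot=200, seed=7)
    ci2 = bootstrap_auc_ci(scores, labels, n_boot=200, seed=7)
    assert ci1 == ci2 == (1.0, 1.0)
    with pytest.raises(DataError):
        bootstrap_auc_ci(scores[:4], labels[:4], seed=0)  # < 3 controls


def test_roc_with_ci_brackets_the_point_estimate():
    rng = np.random.default_rng(1)
    scores = _series(np.concatenate([rng.normal(-1, 1, 20), rng.normal(0, 1, 20)]))
    labels = [True] * 20 + [False] * 20
    res = roc_with_ci(scores, labels, n_boot=500, seed=3)
    lo, hi = res.ci95
    assert lo <= res.auc <= hi


def test_rank_biomarkers_strict_threshold_and_ordering():
    def mk(mid, auc):
        r = roc_analysis(
            _series([2.0, 1.0, -1.0, -2.0]), [True, True, False, False], orientation="high"
        )
        r.mirna_id, r.auc = mid, auc
        return r

    results = [mk("b", 0.9), mk("a", 0.9), mk("edge", 0.8), mk("low", 0.6)]
    ranked = rank_biomarkers(results, auc_threshold=0.8)
    assert [r.mirna_id for r in ranked] == ["a", "b"]  # 0.8 excluded (strict >)
    assert rank_biomarkers([], auc_threshold=0.8) == []
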