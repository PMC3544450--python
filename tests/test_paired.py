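"""Paired pre/post fold changes and the recurrence criterion."""

import numpy as np
import pandas as pd
import pytest

from mirserum import MetadataError, paired_fold_changes, recurrence_filter

from conftest import make_metadata, make_norm


def _paired_norm(pre_rows, post_rows, n_pairs=None):
    """Build a paired cohort: one PRE and one POST column per patient."""
    pre_rows = np.atleast_2d(np.asarray(pre_rows, dtype=float))
    post_rows = np.atleast_2d(np.asarray(post_rows, dtype=float))
    n_pairs = n_pairs or pre_rows.shape[1]
    cols, groups, tps, patients = [], [], [], []
    data = np.empty((pre_rows.shape[0], 2 * n_pairs))
    for j in range(n_pairs):
        cols += [f"P{j}-PRE", f"P{j}-POST"]
        groups += ["OSCC", "OSCC"]
        tps += ["PRE", "POST"]
        patients += [f"P{j}", f"P{j}"]
        data[:, 2 * j] = pre_rows[:, j]
        data[:, 2 * j + 1] = post_rows[:, j]
    frame = pd.DataFrame(data, index=[f"m{i}" for i in range(pre_rows.shape[0])], columns=cols)
    meta = make_metadata(groups, ids=cols, timepoints=tps, patients=patients)
    return make_norm(frame), meta


def test_one_cycle_difference_is_exactly_twofold():
    # ΔCp pre = -1, post = 0: the miRNA was one cycle more abundant
    # before surgery, i.e. linear fold change exactly 2.0
    norm, meta = _paired_norm([[-1.0, -1.0, -1.0]], [[0.0, 0.0, 0.0]])
    pfc = paired_fold_changes(norm, meta)
    assert (2.0 ** pfc.log2fc.loc["m0"] == 2.0).all()
    assert pfc.fraction_up["m0"] == 0.0  # strict > 2 excludes exactly 2.0


def test_identical_pre_post_gives_fold_change_one():
    norm, meta = _paired_norm([[0.3, -0.2, 1.0]], [[0.3, -0.2, 1.0]])
    pfc = paired_fold_changes(norm, meta)
    assert np.allclose(2.0 ** pfc.log2fc.loc["m0"].to_numpy(), 1.0)


def test_eight_of_ten_pairs_above_twofold():
    pre = [[-2.0] * 8 + [0.0] * 2]
    post = [[0.0] * 10]
    norm, meta = _paired_norm(pre, post)
    pfc = paired_fold_changes(norm, meta)
    assert pfc.fraction_up["m0"] == pytest.approx(0.8)
    assert pfc.n_evaluable["m0"] == 10


def test_undetected_member_excluded_from_denominator():
    pre = [[-2.0, -2.0, np.nan, -2.0]]
    post = [[0.0, np.nan, 0.0, 0.0]]
    norm, meta = _paired_norm(pre, post)
    pfc = paired_fold_changes(norm, meta)
    assert pfc.n_evaluable["m0"] == 2
    assert pfc.fraction_up["m0"] == pytest.approx(1.0)


def test_antisymmetry_swapping_pre_and_post():
    rng = np.random.default_rng(0)
    pre = rng.normal(0, 1.5, (12, 6))
    post = rng.normal(0, 1.5, (12, 6))
    fwd, meta_f = _paired_norm(pre, post)
    rev, meta_r = _paired_norm(post, pre)
    a = paired_fold_changes(fwd, meta_f)
    b = paired_fold_changes(rev, meta_r)
    # f -> 1/f exactly: product of linear fold changes is 1 within 1e-12
    prod = 2.0**a.log2fc.to_numpy() * 2.0**b.log2fc.to_numpy()
    assert np.allclose(prod, 1.0, atol=1e-12)
    pd.testing.assert_series_equal(a.fraction_up, b.fraction_down)
    pd.testing.assert_series_equal(a.fraction_down, b.fraction_up)


def test_pre_without_post_mate_is_metadata_error():
    norm, meta = _paired_norm([[-1.0, -1.0]], [[0.0, 0.0]])
    broken = meta.drop(index=["P1-POST"])
    with pytest.raises(MetadataError, match="P1"):
        paired_fold_changes(norm.copy(), broken)


def test_fewer_than_two_pairs_is_an_error():
    norm, meta = _paired_norm([[-1.0]], [[0.0]])
    with pytest.raises(MetadataError):
        paired_fold_changes(norm, meta)


def test_recurrence_inclusive_boundary_and_ambiguity():
    # 4 pairs: two at +2 cycles (4-fold up), two at -2 (4-fold down):
    # fractions exactly (0.5, 0.5) -> both flags at the inclusive boundary
    norm, meta = _paired_norm([[-2.0, -2.0, 2.0, 2.0]], [[0.0, 0.0, 0.0, 0.0]])
    pfc = paired_fold_changes(norm, meta)
    with pytest.warns(UserWarning, match="up AND down"):
        flags = recurrence_filter(pfc, fc_threshold=2.0, frac_threshold=0.5)
    assert bool(flags.loc["m0", "recurrently_up"])
    assert bool(flags.loc["m0", "recurrently_down"])
    assert bool(flags.loc["m0", "ambiguous"])


def test_recurrence_neither_flag_for_flat_profiles():
    norm, meta = _paired_norm([[0.1, -0.1, 0.0]], [[0.1, -0.1, 0.0]])
    flags = recurrence_filter(paired_fold_changes(norm, meta))
    assert not flags.loc["m0", "recurrently_up"]
    assert not flags.loc["m0", "recurrently_down"]


def test_exponent_order_flip_inverts_fold_changes():
    norm, meta = _paired_norm([[-1.0, -2.0, 0.5]], [[0.0, 0.0, 0.0]])
    default = paired_fold_changes(norm, meta)
    literal = paired_fold_changes(norm, meta, exponent="pre_minus_post")
    assert np.allclose(
        default.log2fc.to_numpy(), -literal.log2fc.to_numpy()
    )
    with pytest.raises(ValueError):
        paired_fold_changes(norm, meta, exponent="sideways")


def test_recurrence_half_boundary_is_inclusive():
    norm, meta = _paired_norm([[-2.0, -2.0, 0.0, 0.0]], [[0.0, 0.0, 0.0, 0.0]])
    flags = recurrence_filter(paired_fold_changes(norm, meta), frac_threshold=0.5)
    assert bool(flags.loc["m0", "recurrently_up"])  # fraction exactly 0.5
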