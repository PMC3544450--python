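"""Permutation-based differential expression and three-group contrasts.

Two-group testing (high-risk lesion vs control) uses a label-permutation
test on the difference of group mean ΔCp.  The statistic is

    T(m) = mean ΔCp(m, disease) − mean ΔCp(m, control)

over the *detected* cells of miRNA ``m``; because lower ΔCp means more
abundant, ``T < 0`` indicates upregulation in disease.  The null is built
by permuting sample group labels, applying the **same** permutation to
every miRNA in an iteration, which preserves inter-miRNA correlation of
the null while leaving each marginal null exact.  Two-sided p-values use
the add-one estimator p = (1 + #{|T_perm| ≥ |T_obs|}) / (1 + B), which is
a valid p-value and never zero.

Only miRNAs detected in at least ``min_detection`` (default 60%) of the
samples are tested; the Benjamini–Hochberg family is exactly the tested
set.  An exhaustive enumerator over all group assignments serves as the
exact oracle for small cohorts.

Three-group structure (CIS vs OSCC vs control) is characterized by
one-way ANOVA with BH correction and Tukey-HSD post-hoc contrasts,
summarized into a contrast-pattern label per miRNA.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    DISEASE_GROUPS,
    DataError,
    MetadataError,
    NormalizedMatrix,
    SizeError,
    validate_metadata,
)

#: Enumeration guards for the exhaustive oracle.
MAX_EXHAUSTIVE_SAMPLES = 20
MAX_EXHAUSTIVE_COMBINATIONS = 200_000

PATTERNS = ("CIS_SPECIFIC", "OSCC_SPECIFIC", "SHARED", "CIS_VS_BOTH", "NONE")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.isnan(p).any() or (p <= 0).any() or (p > 1).any()):
        raise DataError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _as_frame(norm) -> pd.DataFrame:
    return norm.values if isinstance(norm, NormalizedMatrix) else pd.DataFrame(norm)


def _two_group_setup(norm, meta, min_detection):
    """Gate miRNAs, split samples into disease/control, drop degenerate rows."""
    values = _as_frame(norm)
    meta = validate_metadata(meta)
    missing = values.columns.difference(meta.index)
    if len(missing):
        raise MetadataError(f"metadata missing for sample(s): {list(missing)[:5]}")
    meta = meta.reindex(values.columns)
    is_dis = meta["group"].isin(DISEASE_GROUPS).to_numpy()
    if is_dis.sum() == 0 or (~is_dis).sum() == 0:
        raise MetadataError("both a disease and a control group are required")

    det = values.notna()
    gated = det.mean(axis=1) >= min_detection
    values, det = values[gated], det[gated]

    cnt_d = det.to_numpy().astype(np.int64) @ is_dis.astype(np.int64)
    cnt_c = det.to_numpy().astype(np.int64) @ (~is_dis).astype(np.int64)
    degenerate = (cnt_d == 0) | (cnt_c == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gated miRNA(s) have no detected value in one "
            "group and are excluded from testing"
        )
        values, det = values[~degenerate], det[~degenerate]
    return values, det, is_dis


def _stats_for_assignments(values, det, assign):
    """Mean-difference statistics for each column of a 0/1 assignment matrix.

    ``assign`` has shape (n_samples, B); column b marks which samples play
    the disease role.  Returns an (n_mirnas, B) array, NaN where an
    assignment leaves a group with no detected cell for that miRNA.
    """
    X = np.nan_to_num(values.to_numpy(), nan=0.0)
    M = det.to_numpy().astype(float)
    A = assign.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_d = (X @ A) / (M @ A)
        mean_c = (X @ (1.0 - A)) / (M @ (1.0 - A))
    return mean_d - mean_c


def _results_frame(values, det, is_dis, t_obs, p_raw, n_permutations, seed):
    res = pd.DataFrame(
        {
            "n_detected_disease": det.to_numpy().astype(np.int64) @ is_dis.astype(np.int64),
            "n_detected_control": det.to_numpy().astype(np.int64) @ (~is_dis).astype(np.int64),
            "statistic": t_obs,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
            "direction": np.where(t_obs < 0, "UP", "DOWN"),
        },
        index=values.index,
    )
    res.attrs["n_permutations"] = n_permutations
    res.attrs["seed"] = seed
    return res


def permutation_test(
    norm,
    meta: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
    min_detection: float = 0.6,
) -> pd.DataFrame:
    """Monte-Carlo permutation test of disease vs control mean ΔCp.

    Returns a DataFrame indexed by miRNA id with columns
    ``n_detected_disease``, ``n_detected_control``, ``statistic``
    (disease − control mean ΔCp, cycles), ``p_raw``, ``p_adj`` (BH over
    the tested family) and ``direction`` (``UP`` = more abundant in
    disease, i.e. statistic < 0).  The permutation count and seed travel
    in ``result.attrs``.
    """
    values, det, is_dis = _two_group_setup(norm, meta, min_detection)
    t_obs = _stats_for_assignments(values, det, is_dis[:, None].astype(float))[:, 0]

    rng = np.random.default_rng(seed)
    n = len(is_dis)
    perm_cols = np.empty((n, n_permutations))
    for b in range(n_permutations):
        perm_cols[:, b] = is_dis[rng.permutation(n)]
    t_perm = _stats_for_assignments(values, det, perm_cols)

    valid = np.isfinite(t_perm)
    exceed = np.nansum((np.abs(t_perm) >= np.abs(t_obs)[:, None]) & valid, axis=1)
    n_valid = valid.sum(axis=1)
    p_raw = (1.0 + exceed) / (1.0 + n_valid)
    return _results_frame(values, det, is_dis, t_obs, p_raw, n_permutations, seed)


def exhaustive_permutation_test(
    norm, meta: pd.DataFrame, min_detection: float = 0.6
) -> pd.DataFrame:
    """Exact permutation test enumerating every group assignment.

    Enumerates all C(n, k) ways to assign the disease label; the p-value
    is the exact fraction of assignments (including the observed one)
    whose |statistic| is at least the observed.  Guarded to ≤ 20 samples
    and ≤ 200,000 assignments.
    """
    values, det, is_dis = _two_group_setup(norm, meta, min_detection)
    n, k = len(is_dis), int(is_dis.sum())
    n_comb = math.comb(n, k)
    if n > MAX_EXHAUSTIVE_SAMPLES or n_comb > MAX_EXHAUSTIVE_COMBINATIONS:
        raise SizeError(
            f"exhaustive enumeration of C({n},{k}) = {n_comb} assignments exceeds "
            f"the guard ({MAX_EXHAUSTIVE_SAMPLES} samples, "
            f"{MAX_EXHAUSTIVE_COMBINATIONS} combinations)"
        )
    t_obs = _stats_for_assignments(values, det, is_dis[:, None].astype(float))[:, 0]

    assign = np.zeros((n, n_comb))
    for b, combo in enumerate(itertools.combinations(range(n), k)):
        assign[list(combo), b] = 1.0
    t_all = _stats_for_assignments(values, det, assign)

    valid = np.isfinite(t_all)
    exceed = np.nansum((np.abs(t_all) >= np.abs(t_obs)[:, None]) & valid, axis=1)
    p_raw = exceed / valid.sum(axis=1)
    return _results_frame(values, det, is_dis, t_obs, p_raw, n_comb, None)


def classify_pattern(cis_ctrl: bool, oscc_ctrl: bool, cis_oscc: bool) -> str:
    """Map the three Tukey significance flags to a contrast-pattern label."""
    if cis_ctrl and not oscc_ctrl and not cis_oscc:
        return "CIS_SPECIFIC"
    if cis_ctrl and cis_oscc and not oscc_ctrl:
        return "CIS_VS_BOTH"
    if cis_ctrl and oscc_ctrl and not cis_oscc:
        return "SHARED"
    if oscc_ctrl and not cis_ctrl and not cis_oscc:
        return "OSCC_SPECIFIC"
    return "NONE"


def anova_tukey_classify(
    norm,
    meta: pd.DataFrame,
    min_detection: float = 0.6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA across CIS/OSCC/control with Tukey-HSD patterns.

    Per gated miRNA, ANOVA is run on the detected ΔCp of the three
    groups; p-values are BH-corrected over the tested family, and Tukey
    HSD pairwise contrasts (at ``alpha``) are evaluated for miRNAs with
    adjusted p below ``alpha``.  Each miRNA gets a pattern label — see
    :func:`classify_pattern`.  A miRNA with fewer than two detected
    values in any group is labeled ``NONE`` with a warning.
    """
    values = _as_frame(norm)
    meta = validate_metadata(meta).reindex(values.columns)
    groups = meta["group"]
    present = set(groups.unique())
    if not {"CIS", "OSCC", "CONTROL"} <= present:
        raise MetadataError(f"three groups required, found {sorted(present)}")

    det = values.notna()
    gated = det.mean(axis=1) >= min_detection
    values = values[gated]

    rows, skipped = {}, 0
    for mirna, row in values.iterrows():
        per_group = [row[(groups == g).to_numpy()].dropna() for g in ("CIS", "OSCC", "CONTROL")]
        if min(len(v) for v in per_group) < 2:
            skipped += 1
            rows[mirna] = dict(p_anova=np.nan)
            continue
        rows[mirna] = dict(p_anova=stats.f_oneway(*[v.to_numpy() for v in per_group]).pvalue)
    if skipped:
        warnings.warn(f"{skipped} miRNA(s) with <2 detected values in a group; labeled NONE")

    res = pd.DataFrame.from_dict(rows, orient="index").reindex(values.index)
    tested = res["p_anova"].notna()
    res["p_adj"] = np.nan
    res.loc[tested, "p_adj"] = bh_adjust(res.loc[tested, "p_anova"].to_numpy())

    flags = pd.DataFrame(
        False,
        index=res.index,
        columns=["sig_cis_vs_control", "sig_oscc_vs_control", "sig_cis_vs_oscc"],
    )
    for mirna in res.index[tested & (res["p_adj"] < alpha)]:
        row = values.loc[mirna]
        mask = row.notna().to_numpy()
        hsd = pairwise_tukeyhsd(row.to_numpy()[mask], groups.to_numpy()[mask], alpha=alpha)
        by_pair = {
            frozenset(pair): bool(rej)
            for pair, rej in zip(
                itertools.combinations(hsd.groupsunique, 2), np.atleast_1d(hsd.reject)
            )
        }
        flags.loc[mirna] = [
            by_pair.get(frozenset(("CIS", "CONTROL")), False),
            by_pair.get(frozenset(("OSCC", "CONTROL")), False),
            by_pair.get(frozenset(("CIS", "OSCC")), False),
        ]
    res = res.join(flags)
    res["pattern"] = [
        classify_pattern(r.sig_cis_vs_control, r.sig_oscc_vs_control, r.sig_cis_vs_oscc)
        for r in res.itertuples()
    ]
    return res
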