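"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive (pair counting, enumeration,
closed-form tails, hand arithmetic) and never call the code paths they
check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from mirserum import CpMatrix, NormalizedMatrix


def make_metadata(
    groups,
    ids=None,
    timepoints=None,
    patients=None,
    hemolyzed=None,
    plates=None,
) -> pd.DataFrame:
    """Build a minimal valid metadata table."""
    n = len(groups)
    ids = ids or [f"S{i:02d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "group": list(groups),
            "patient_id": patients or [f"P{i:02d}" for i in range(n)],
            "timepoint": timepoints or ["NONE"] * n,
            "hemolyzed": hemolyzed if hemolyzed is not None else [False] * n,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    if plates is not None:
        meta["plate"] = list(plates)
    return meta


def make_norm(values: pd.DataFrame, plates=None) -> NormalizedMatrix:
    """Wrap an arbitrary ΔCp frame (zero-mean not enforced; tests own it)."""
    values = pd.DataFrame(values, dtype=float)
    if plates is None:
        plates = pd.Series("plate-1", index=values.columns)
    return NormalizedMatrix(
        values=values,
        plates=plates,
        sample_global_mean=pd.Series(np.nan, index=values.columns),
    )


def make_cp(values: pd.DataFrame, plates=None, calibrator_ids=()) -> CpMatrix:
    values = pd.DataFrame(values, dtype=float)
    if plates is None:
        plates = pd.Series("plate-1", index=values.columns)
    return CpMatrix(values, pd.Series(plates), tuple(calibrator_ids))


# ----------------------------------------------------------------- oracles


def bh_oracle(p):
    """Brute-force Benjamini–Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        adj[idx] = min(1.0, min(candidates))
    return adj


def auc_pair_oracle(pos, neg) -> float:
    """Concordance probability by explicit pair counting (ties count ½)."""
    wins = sum(
        1.0 if a > b else 0.5 if a == b else 0.0
        for a in pos
        for b in neg
    )
    return wins / (len(pos) * len(neg))


def exhaustive_p_oracle(values, is_disease) -> np.ndarray:
    """Exact permutation p for the mean-difference statistic, one miRNA row
    at a time, by naive enumeration of label assignments."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    n = values.shape[1]
    k = int(np.sum(is_disease))
    out = []
    for row in values:
        det = ~np.isnan(row)

        def stat(mask):
            d = row[mask & det]
            c = row[~mask & det]
            if len(d) == 0 or len(c) == 0:
                return np.nan
            return d.mean() - c.mean()

        obs = stat(np.asarray(is_disease, bool))
        stats = []
        for combo in itertools.combinations(range(n), k):
            mask = np.zeros(n, bool)
            mask[list(combo)] = True
            stats.append(stat(mask))
        stats = np.array(stats)
        valid = np.isfinite(stats)
        out.append(np.sum(np.abs(stats[valid]) >= abs(obs)) / valid.sum())
    return np.asarray(out)
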