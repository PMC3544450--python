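"""ROC analysis, bootstrap AUC confidence intervals, and marker ranking.

AUC is computed by the trapezoid rule over the empirical ROC curve (ties
stepped simultaneously), which equals the normalized Mann–Whitney
rank-sum statistic: the probability that a random disease sample scores
above a random control, ties counting ½.  The operating point maximizes
Youden's J = sensitivity + specificity − 1, ties broken toward higher
specificity.  Confidence intervals use a stratified percentile bootstrap
(resampling within class), the assumption-light choice for small serum
cohorts.

Orientation: candidate markers can be up- or downregulated in disease;
with ``orientation="auto"`` the score sign is chosen so AUC ≥ 0.5 and
the flip is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .datatypes import DataError


def mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the normalized rank-sum: P(pos > neg) + ½ P(pos = neg)."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


@dataclass
class RocResult:
    """ROC curve and summaries for one candidate miRNA."""

    mirna_id: str
    low_dcp_is_disease: bool  # True: low ΔCp (abundant) scored as disease
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    sensitivity: float
    specificity: float
    threshold: float  # operating ΔCp cutoff
    n_disease: int
    n_control: int
    n_excluded: int
    ci95: tuple[float, float] | None = None


def roc_analysis(
    scores: pd.Series,
    labels,
    orientation: str = "auto",
    mirna_id: str = "",
) -> RocResult:
    """ROC curve and Youden operating point for one marker.

    ``scores`` are per-sample ΔCp values (NaN = undetected, excluded with
    the count reported); ``labels`` is a boolean disease indicator
    aligned with ``scores``.  ``orientation``: ``"auto"`` picks the score
    sign giving AUC ≥ 0.5; ``"low"`` / ``"high"`` fix whether low or high
    ΔCp scores as disease.
    """
    scores = pd.Series(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(y) != len(scores):
        raise DataError("scores and labels differ in length")
    keep = scores.notna().to_numpy()
    n_excluded = int((~keep).sum())
    s, y = scores.to_numpy()[keep], y[keep]
    if y.all() or not y.any():
        raise DataError("both disease and control samples are required")

    if orientation == "auto":
        low = mann_whitney_auc(-s[y], -s[~y]) >= 0.5
    elif orientation in ("low", "high"):
        low = orientation == "low"
    else:
        raise ValueError(f"orientation must be auto|low|high, got {orientation!r}")
    signed = -s if low else s  # higher signed score = more disease-like

    if np.ptp(s) == 0:
        warnings.warn(f"all scores identical for {mirna_id or 'marker'}; degenerate ROC")
    fpr, tpr, thresholds = roc_curve(y, signed)
    auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    best = int(np.argmax(j))  # first max: smallest FPR, i.e. highest specificity
    thr = thresholds[best]
    if np.isinf(thr):  # sklearn's sentinel above the largest score
        thr = signed.max() + 1.0
    return RocResult(
        mirna_id=mirna_id,
        low_dcp_is_disease=low,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        threshold=float(-thr if low else thr),
        n_disease=int(y.sum()),
        n_control=int((~y).sum()),
        n_excluded=n_excluded,
    )


def bootstrap_auc_ci(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified percentile-bootstrap 95% CI for the AUC.

    Scores must already be oriented (higher = more disease-like).  Both
    classes need at least 3 members.  Deterministic under a fixed seed.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    if len(pos) < 3 or len(neg) < 3:
        raise DataError("bootstrap CI requires >= 3 samples per class")
    rng = np.random.default_rng(seed)
    bp = pos[rng.integers(0, len(pos), (n_boot, len(pos)))]
    bn = neg[rng.integers(0, len(neg), (n_boot, len(neg)))]
    ranks = rankdata(np.concatenate([bp, bn], axis=1), axis=1)
    u = ranks[:, : len(pos)].sum(axis=1) - len(pos) * (len(pos) + 1) / 2
    aucs = u / (len(pos) * len(neg))
    lo, hi = np.quantile(aucs, [0.025, 0.975])
    return float(lo), float(hi)


def roc_with_ci(
    scores: pd.Series,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    mirna_id: str = "",
) -> RocResult:
    """ROC analysis plus a bootstrap CI on the oriented scores."""
    res = roc_analysis(scores, labels, orientation="auto", mirna_id=mirna_id)
    keep = pd.Series(scores, dtype=float).notna().to_numpy()
    s = np.asarray(scores, float)[keep]
    y = np.asarray(labels, bool)[keep]
    signed = -s if res.low_dcp_is_disease else s
    res.ci95 = bootstrap_auc_ci(signed, y, n_boot=n_boot, seed=seed)
    return res


def rank_biomarkers(
    roc_results: list[RocResult], auc_threshold: float = 0.8
) -> list[RocResult]:
    """Markers with AUC strictly above threshold, best first; ties by id."""
    passing = [r for r in roc_results if r.auc > auc_threshold]
    return sorted(passing, key=lambda r: (-r.auc, r.mirna_id))


def roc_table(roc_results: list[RocResult]) -> pd.DataFrame:
    """Flat summary table of ROC results (one row per marker)."""
    rows = []
    for r in roc_results:
        lo, hi = r.ci95 if r.ci95 is not None else (np.nan, np.nan)
        rows.append(
            {
                "mirna_id": r.mirna_id,
                "auc": r.auc,
                "ci95_low": lo,
                "ci95_high": hi,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "threshold_dcp": r.threshold,
                "low_dcp_is_disease": r.low_dcp_is_disease,
                "n_disease": r.n_disease,
                "n_control": r.n_control,
                "n_excluded": r.n_excluded,
            }
        )
    return pd.DataFrame(rows).set_index("mirna_id") if rows else pd.DataFrame(
        columns=["auc"], index=pd.Index([], name="mirna_id")
    )
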