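"""Assay- and sample-level quality control for Cp panels.

Three censoring rules turn unreliable reactions into the undetected
state, applied in a fixed order so every censored cell is attributed to
exactly one rule:

1. *multi-Tm*: more than one melting-temperature peak (nonspecific
   amplification);
2. *Cp cap*: Cp above the fixed detection cap (default 35 cycles);
3. *near negative control*: Cp within 5 cycles of the plate's
   no-template control (an undetected negative control is treated as the
   instrument maximum of 40 cycles, which makes this rule coincide with
   the 35-cycle cap).

Sample-level QC removes hemolyzed sera: red-cell lysis releases cellular
miRNAs and distorts the circulating profile, so flagged samples are
excluded outright.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CYCLE_MAX, AssayQC, CpMatrix, DataError, validate_metadata

#: Fixed detection cap (cycles): reactions above this Cp are censored.
CP_CAP = 35.0

#: Margin (cycles) below the negative control within which a Cp is censored.
NEG_CONTROL_MARGIN = 5.0


def filter_assays(
    matrix: CpMatrix,
    qc: AssayQC,
    cp_cap: float = CP_CAP,
    neg_control_margin: float = NEG_CONTROL_MARGIN,
) -> tuple[CpMatrix, dict[str, int]]:
    """Censor unreliable reactions; return the filtered matrix and rule counts.

    The returned counts partition the newly censored cells by the first
    rule that caught them, keys ``multi_tm``, ``cp_above_cap``,
    ``near_negative_control``.  The operation is idempotent and never
    converts an undetected cell back to numeric.
    """
    values = matrix.values.copy()
    numeric = values.notna().to_numpy()

    melt = qc.melt_peaks.reindex(index=values.index, columns=values.columns)
    uncovered = numeric & melt.isna().to_numpy()
    if uncovered.any():
        i, j = map(int, np.argwhere(uncovered)[0])
        raise DataError(
            f"melt-peak QC missing for detected cell ({values.index[i]}, {values.columns[j]})"
        )

    neg = matrix.plates.map(qc.negative_control_cp).astype(float)
    # undetected negative control: conservatively assume the cycle maximum
    neg = neg.fillna(CYCLE_MAX)
    neg_row = neg.to_numpy()[None, :]

    arr = values.to_numpy()
    rule_multi = numeric & (melt.to_numpy(dtype=float) > 1)
    rule_cap = numeric & ~rule_multi & (arr > cp_cap)
    rule_neg = numeric & ~rule_multi & ~rule_cap & (arr > neg_row - neg_control_margin)

    counts = {
        "multi_tm": int(rule_multi.sum()),
        "cp_above_cap": int(rule_cap.sum()),
        "near_negative_control": int(rule_neg.sum()),
    }
    arr[rule_multi | rule_cap | rule_neg] = np.nan
    filtered = CpMatrix(
        pd.DataFrame(arr, index=values.index, columns=values.columns),
        matrix.plates,
        matrix.calibrator_ids,
    )
    return filtered, counts


def drop_hemolyzed(
    matrix: CpMatrix, meta: pd.DataFrame
) -> tuple[CpMatrix, pd.DataFrame, int]:
    """Remove hemolysis-flagged samples from the matrix and metadata.

    Returns ``(matrix, metadata, n_removed)``.  Zero flagged samples is a
    no-op; removing every sample is legal but warned about.
    """
    meta = validate_metadata(meta)
    missing = matrix.sample_ids.difference(meta.index)
    if len(missing):
        raise DataError(f"metadata missing for sample(s): {list(missing)[:5]}")
    keep = [s for s in matrix.sample_ids if not meta.loc[s, "hemolyzed"]]
    n_removed = len(matrix.sample_ids) - len(keep)
    if not keep:
        warnings.warn("all samples flagged hemolyzed; returning an empty matrix")
    out = CpMatrix(matrix.values[keep], matrix.plates[keep], matrix.calibrator_ids)
    return out, meta.loc[keep], n_removed


@dataclass
class DetectionSummary:
    """Per-miRNA detection fractions and panel-level detection counts."""

    fraction_overall: pd.Series
    fraction_by_group: pd.DataFrame
    n_detected_ge1: int
    n_detected_all: int


def detection_summary(matrix: CpMatrix, meta: pd.DataFrame) -> DetectionSummary:
    """Detection accounting over the miRNA rows (calibrators excluded).

    ``n_detected_ge1`` counts miRNAs detected in at least one sample,
    ``n_detected_all`` those detected in every sample.
    """
    values = matrix.mirna_values
    if values.empty:
        raise DataError("detection summary of an empty matrix")
    det = values.notna()
    frac = det.mean(axis=1)
    meta = validate_metadata(meta).reindex(matrix.sample_ids)
    by_group = {
        g: det.loc[:, (meta["group"] == g).to_numpy()].mean(axis=1)
        for g in meta["group"].unique()
    }
    return DetectionSummary(
        fraction_overall=frac,
        fraction_by_group=pd.DataFrame(by_group),
        n_detected_ge1=int((det.sum(axis=1) >= 1).sum()),
        n_detected_all=int(det.all(axis=1).sum()),
    )
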