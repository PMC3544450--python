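"""Interplate calibration and global-mean ΔCp normalization.

Serum panels carry no reliable endogenous reference gene, so each sample
is centered on the mean Cp of **all its detected miRNAs** (global-mean
normalization): ΔCp(m, s) = Cp(m, s) − mean_m′ Cp(m′, s).  Every
normalized sample therefore has mean ΔCp exactly zero over its detected
set, and any per-sample additive artifact (pipetting volume, input RNA
amount, plate offset uniform within the sample) cancels.

Plate-to-plate Cp offsets are removed first using the interplate
calibrator assays replicated on every plate: each plate's cells are
shifted so that plate calibrator means agree with the grand mean of the
per-plate calibrator means.  Calibration precedes normalization.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CalibrationError,
    CpMatrix,
    NormalizationError,
    NormalizedMatrix,
)


def interplate_calibrate(
    matrix: CpMatrix, calibrator_ids: Sequence[str] | None = None
) -> tuple[CpMatrix, pd.Series]:
    """Remove per-plate Cp offsets using calibrator assays.

    For each plate, offset = (mean calibrator Cp on that plate) − (grand
    mean of the per-plate calibrator means); the offset is subtracted
    from every numeric cell of that plate.  With a single plate, or with
    identical calibrator means, this is the identity.

    Returns ``(calibrated matrix, per-plate offsets)``.
    """
    if calibrator_ids is None:
        calibrator_ids = matrix.calibrator_ids
    calibrator_ids = list(calibrator_ids)
    if not calibrator_ids:
        raise CalibrationError("no calibrator assays given")
    missing = set(calibrator_ids) - set(matrix.values.index)
    if missing:
        raise CalibrationError(f"calibrator id(s) not in matrix: {sorted(missing)}")

    cal = matrix.values.loc[calibrator_ids]
    plate_means = {}
    for plate, samples in matrix.plates.groupby(matrix.plates).groups.items():
        block = cal[list(samples)]
        if block.notna().to_numpy().sum() == 0:
            raise CalibrationError(f"plate {plate!r} has no detected calibrator value")
        plate_means[plate] = float(np.nanmean(block.to_numpy()))
    grand = float(np.mean(list(plate_means.values())))
    offsets = pd.Series({p: m - grand for p, m in plate_means.items()}, name="offset")

    shift = matrix.plates.map(offsets).to_numpy()[None, :]
    calibrated = matrix.values - shift  # NaN cells stay NaN
    return (
        CpMatrix(calibrated, matrix.plates, matrix.calibrator_ids),
        offsets,
    )


def global_mean_normalize(
    matrix: CpMatrix,
    plate_offsets: pd.Series | None = None,
    expressed: str = "per_sample",
) -> NormalizedMatrix:
    """Center each sample on the mean Cp of its detected miRNAs.

    Calibrator rows are excluded from both the mean and the output.  The
    undetected pattern is preserved.  A sample with no detected miRNA has
    no defined global mean and raises :class:`NormalizationError`.

    ``expressed`` selects the reference set: ``"per_sample"`` (default)
    averages each sample's own detected miRNAs — robust to panel
    dropouts; ``"shared"`` averages only miRNAs detected in every
    sample, trading robustness for an identical reference set across
    samples.
    """
    if expressed not in ("per_sample", "shared"):
        raise ValueError(f"unknown expressed set {expressed!r}")
    values = matrix.mirna_values
    n_det = values.notna().sum(axis=0)
    empty = n_det[n_det == 0]
    if len(empty):
        raise NormalizationError(
            f"sample(s) with zero detected miRNAs: {list(empty.index)[:5]}"
        )
    if expressed == "shared":
        shared = values.dropna(axis=0)
        if shared.empty:
            raise NormalizationError("no miRNA is detected in every sample")
        global_mean = shared.mean(axis=0)
    else:
        global_mean = values.mean(axis=0, skipna=True)
    delta = values.sub(global_mean, axis=1)
    return NormalizedMatrix(
        values=delta,
        plates=matrix.plates.copy(),
        sample_global_mean=global_mean.rename("global_mean_cp"),
        plate_offsets=plate_offsets,
    )
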