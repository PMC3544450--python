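"""Core containers and error types for serum qPCR panel analysis.

The central object is a Cp matrix: quantification-cycle values for a panel
of miRNA assays (rows) across serum samples (columns).  A cell is either a
finite Cp in ``(0, 40]`` cycles or *undetected* — the assay never crossed
the fluorescence threshold, or was censored by QC.  Undetected cells are
stored as ``NaN`` in a float DataFrame; they are an explicit state, not a
number, and every downstream computation treats them as missing rather
than imputing a value.

Sign convention used throughout: **lower Cp means more template, i.e.
higher expression**, and after global-mean normalization lower ΔCp means
relatively more abundant within the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Instrument cycle maximum; Cp values are only meaningful in (0, CYCLE_MAX].
CYCLE_MAX = 40.0

GROUPS = ("CIS", "OSCC", "CONTROL")
DISEASE_GROUPS = ("CIS", "OSCC")
TIMEPOINTS = ("PRE", "POST", "NONE")
META_COLUMNS = ("group", "patient_id", "timepoint", "hemolyzed")


class MirserumError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(MirserumError):
    """Invalid configuration (simulation or pipeline parameters)."""


class DataError(MirserumError):
    """Malformed or inconsistent input data."""


class MetadataError(MirserumError):
    """Sample metadata violates its contract (groups, pairing, coverage)."""


class CalibrationError(MirserumError):
    """Interplate calibration cannot be performed (e.g. plate without calibrator)."""


class NormalizationError(MirserumError):
    """Global-mean normalization undefined (e.g. sample with no detections)."""


class SizeError(MirserumError):
    """Problem size exceeds an exhaustive-enumeration guard."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise DataError(f"duplicate {what} identifier(s): {dup[:5]}")


@dataclass
class CpMatrix:
    """Raw or calibrated Cp values, miRNA assays × samples.

    Parameters
    ----------
    values
        Float DataFrame, rows indexed by assay id, columns by sample id.
        ``NaN`` encodes the undetected state; every numeric entry must lie
        in ``(0, CYCLE_MAX]``.
    plates
        Series mapping sample id → plate identifier.
    calibrator_ids
        Row ids that are interplate calibrator assays rather than miRNAs.
        They participate in plate calibration only and are excluded from
        detection accounting, normalization and testing.
    """

    values: pd.DataFrame
    plates: pd.Series
    calibrator_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "miRNA")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        numeric = ~np.isnan(arr)
        if numeric.any():
            bad = numeric & ~((arr > 0) & (arr <= CYCLE_MAX))
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise DataError(
                    f"Cp value {arr[i, j]!r} for ({self.values.index[i]}, "
                    f"{self.values.columns[j]}) outside (0, {CYCLE_MAX}]"
                )
        self.plates = pd.Series(self.plates)
        missing = self.values.columns.difference(self.plates.index)
        if len(missing):
            raise DataError(f"no plate assignment for sample(s): {list(missing)[:5]}")
        self.plates = self.plates.reindex(self.values.columns)
        unknown_cal = set(self.calibrator_ids) - set(self.values.index)
        if unknown_cal:
            raise DataError(f"calibrator id(s) not in matrix: {sorted(unknown_cal)}")
        self.calibrator_ids = tuple(self.calibrator_ids)

    @property
    def mirna_ids(self) -> pd.Index:
        """Assay rows that are miRNAs (calibrator rows excluded)."""
        return self.values.index.difference(pd.Index(self.calibrator_ids), sort=False)

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def mirna_values(self) -> pd.DataFrame:
        """The miRNA submatrix, in original row order."""
        keep = [i for i in self.values.index if i not in set(self.calibrator_ids)]
        return self.values.loc[keep]

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected (numeric) cells."""
        return self.values.notna()

    def copy(self) -> "CpMatrix":
        return CpMatrix(self.values.copy(), self.plates.copy(), self.calibrator_ids)


@dataclass
class AssayQC:
    """Per-cell melt-curve QC and per-plate negative controls.

    ``melt_peaks`` counts distinct melting-temperature peaks per reaction
    (a clean single-product amplification has exactly one); it must be
    present for every numeric Cp cell it annotates.  ``negative_control_cp``
    holds the no-template control Cp per plate, ``NaN`` when the control
    never amplified.
    """

    melt_peaks: pd.DataFrame
    negative_control_cp: pd.Series

    def __post_init__(self) -> None:
        self.melt_peaks = pd.DataFrame(self.melt_peaks)
        self.negative_control_cp = pd.Series(self.negative_control_cp, dtype=float)


@dataclass
class NormalizedMatrix:
    """Sample-centered ΔCp values with the normalization record.

    ΔCp(m, s) = Cp(m, s) − mean over the sample's detected miRNAs, so the
    numeric entries of every column average to zero and lower ΔCp means
    relatively more abundant.  The undetected (NaN) pattern is inherited
    unchanged from the input Cp matrix.
    """

    values: pd.DataFrame
    plates: pd.Series
    sample_global_mean: pd.Series
    plate_offsets: pd.Series | None = None

    @property
    def mirna_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def detected(self) -> pd.DataFrame:
        return self.values.notna()

    def copy(self) -> "NormalizedMatrix":
        return NormalizedMatrix(
            self.values.copy(),
            self.plates.copy(),
            self.sample_global_mean.copy(),
            None if self.plate_offsets is None else self.plate_offsets.copy(),
        )


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and return it with normalized dtypes.

    Required columns: ``group`` ∈ {CIS, OSCC, CONTROL}, ``patient_id``,
    ``timepoint`` ∈ {PRE, POST, NONE}, ``hemolyzed`` (boolean).  The index
    is the sample id.  ``(patient_id, timepoint)`` must be unique so that
    matched pre/post samples are unambiguous.
    """
    meta = meta.copy()
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise MetadataError(f"metadata missing column(s): {missing}")
    _check_unique(meta.index, "sample")
    bad_group = set(meta["group"]) - set(GROUPS)
    if bad_group:
        raise MetadataError(f"unknown group value(s): {sorted(bad_group)}; expected {GROUPS}")
    bad_tp = set(meta["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise MetadataError(f"unknown timepoint value(s): {sorted(bad_tp)}; expected {TIMEPOINTS}")
    meta["hemolyzed"] = meta["hemolyzed"].astype(bool)
    dup = meta.duplicated(subset=["patient_id", "timepoint"])
    if dup.any():
        pairs = meta.loc[dup, ["patient_id", "timepoint"]].itertuples(index=False)
        raise MetadataError(f"duplicate (patient_id, timepoint): {list(pairs)[:5]}")
    return meta


def is_disease(meta: pd.DataFrame) -> pd.Series:
    """Boolean Series: True for high-risk-lesion (CIS or OSCC) samples."""
    return meta["group"].isin(DISEASE_GROUPS)
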