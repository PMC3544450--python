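"""Synthetic serum qPCR cohorts with limit-of-detection censoring.

The generator emulates the statistical structure a serum miRNA panel
study assumes: per-assay baseline Cp levels, per-patient random effects,
per-plate offsets, assay noise, disease shifts on a configurable set of
miRNAs, and censoring of any reaction beyond the detection limit.  The
model is additive-normal on the Cp scale with left-truncation-as-missing
at the detection limit — the simplest model that reproduces the censored
structure the QC rules act on.  Disease shifts are applied in cycles, so
a shift of 1.0 corresponds to a 2-fold abundance change by construction
(one PCR cycle doubles template).

Default sizes mirror a two-plate 742-assay panel run on 56 serum samples
(30 high-risk-lesion cases split 14 CIS / 16 OSCC, and 26 controls) with
10 matched pre/post-surgery pairs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AssayQC, ConfigError, CpMatrix, validate_metadata

# Fraction of high-risk-lesion cases that are carcinoma in situ (14 of 30).
_CIS_FRACTION = 14 / 30

#: True level of calibrator assays (cycles); well inside the detected range.
CALIBRATOR_LEVEL = 22.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    All Cp-scale parameters are in cycles.  ``spiked_up`` / ``spiked_down``
    list ``(miRNA index, shift)`` pairs: up-spiked miRNAs are more abundant
    in disease (Cp lowered by ``shift`` in disease samples), down-spiked
    less abundant (Cp raised).
    """

    n_mirnas: int = 742
    n_disease: int = 30
    n_control: int = 26
    n_pairs: int = 10
    baseline_mean_range: tuple[float, float] = (20.0, 34.0)
    assay_sd: float = 0.8
    patient_sd: float = 0.5
    plate_offset_sd: float = 0.3
    n_plates: int = 2
    spiked_up: tuple[tuple[int, float], ...] = ()
    spiked_down: tuple[tuple[int, float], ...] = ()
    detection_limit: float = 35.0
    seed: int = 0
    n_calibrators: int = 3
    n_hemolyzed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirnas", "n_disease", "n_control", "n_pairs", "n_plates"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_calibrators < 0 or self.n_hemolyzed < 0:
            raise ConfigError("n_calibrators and n_hemolyzed must be >= 0")
        lo, hi = self.baseline_mean_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ConfigError(f"invalid baseline_mean_range {self.baseline_mean_range}")
        if not 0 < self.detection_limit <= 40:
            raise ConfigError(
                f"detection_limit {self.detection_limit} outside instrument range (0, 40]"
            )
        for sd_name in ("assay_sd", "patient_sd", "plate_offset_sd"):
            if getattr(self, sd_name) < 0:
                raise ConfigError(f"{sd_name} must be >= 0")
        object.__setattr__(self, "spiked_up", tuple((int(i), float(s)) for i, s in self.spiked_up))
        object.__setattr__(
            self, "spiked_down", tuple((int(i), float(s)) for i, s in self.spiked_down)
        )
        up_idx = {i for i, _ in self.spiked_up}
        down_idx = {i for i, _ in self.spiked_down}
        if up_idx & down_idx:
            raise ConfigError(f"spiked_up and spiked_down overlap: {sorted(up_idx & down_idx)}")
        for i, s in self.spiked_up + self.spiked_down:
            if not 0 <= i < self.n_mirnas:
                raise ConfigError(f"spiked miRNA index {i} out of range [0, {self.n_mirnas})")
            if not np.isfinite(s):
                raise ConfigError(f"spiked shift {s!r} is not finite")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


def spiked_config(
    n_up: int = 10, n_down: int = 10, shift: float = 2.0, **kwargs
) -> SyntheticConfig:
    """Config with ``n_up + n_down`` disease-shifted miRNAs of ``shift`` cycles.

    Spiked assays are placed at evenly spaced panel indices, alternating
    up/down, so the spikes sample the whole baseline-Cp range — including
    assays near the detection limit, where censoring attenuates effects.
    """
    base = SyntheticConfig(**kwargs)
    n_spiked = n_up + n_down
    if n_spiked > base.n_mirnas:
        raise ConfigError("more spiked miRNAs than assays on the panel")
    idx = np.unique(np.linspace(0, base.n_mirnas - 1, n_spiked).round().astype(int))
    if len(idx) < n_spiked:  # tiny panels: fall back to the first indices
        idx = np.arange(n_spiked)
    up = tuple((int(i), float(shift)) for i in idx[0::2][:n_up])
    down = tuple((int(i), float(shift)) for i in idx[1::2][:n_down])
    # alternation may not exhaust both lists when n_up != n_down
    leftover = [int(i) for i in idx if i not in {j for j, _ in up + down}]
    while len(up) < n_up:
        up = up + ((leftover.pop(), float(shift)),)
    while len(down) < n_down:
        down = down + ((leftover.pop(), float(shift)),)
    return base.replace(spiked_up=up, spiked_down=down)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent substreams from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _assay_index(cfg: SyntheticConfig) -> pd.Index:
    width = max(3, len(str(cfg.n_mirnas)))
    return pd.Index([f"mir-{i:0{width}d}" for i in range(cfg.n_mirnas)], name="mirna_id")


def _calibrator_index(cfg: SyntheticConfig) -> pd.Index:
    return pd.Index([f"CAL-{i + 1}" for i in range(cfg.n_calibrators)], name="mirna_id")


def _truth_table(cfg: SyntheticConfig, assays: pd.Index) -> pd.DataFrame:
    rows = [(assays[i], "UP", s) for i, s in cfg.spiked_up]
    rows += [(assays[i], "DOWN", s) for i, s in cfg.spiked_down]
    truth = pd.DataFrame(rows, columns=["mirna_id", "direction", "shift"])
    return truth.sort_values("mirna_id").reset_index(drop=True)


def _round_robin_plates(sample_ids: pd.Index, n_plates: int) -> pd.Series:
    # round-robin guarantees every plate contains samples of every group
    plates = [f"plate-{i % n_plates + 1}" for i in range(len(sample_ids))]
    return pd.Series(plates, index=sample_ids, name="plate")


def _shift_vector(cfg: SyntheticConfig) -> np.ndarray:
    """Per-assay Cp shift applied to disease-state samples (cycles)."""
    shift = np.zeros(cfg.n_mirnas)
    for i, s in cfg.spiked_up:
        shift[i] -= s  # more abundant in disease -> lower Cp
    for i, s in cfg.spiked_down:
        shift[i] += s
    return shift


def _assemble(
    cfg: SyntheticConfig,
    assays: pd.Index,
    sample_ids: pd.Index,
    diseased: np.ndarray,
    patient_effect: np.ndarray,
    rng_base: np.random.Generator,
    rng_plate: np.random.Generator,
    rng_noise: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw the censored Cp matrix (miRNAs + calibrators) and plate map."""
    lo, hi = cfg.baseline_mean_range
    baseline = rng_base.uniform(lo, hi, cfg.n_mirnas)
    plates = _round_robin_plates(sample_ids, cfg.n_plates)
    plate_levels = pd.unique(plates)
    offset_by_plate = dict(
        zip(plate_levels, rng_plate.normal(0.0, cfg.plate_offset_sd, len(plate_levels)))
    )
    plate_offset = plates.map(offset_by_plate).to_numpy()

    n = len(sample_ids)
    cp = (
        baseline[:, None]
        + patient_effect[None, :]
        + plate_offset[None, :]
        + rng_noise.normal(0.0, cfg.assay_sd, (cfg.n_mirnas, n))
    )
    cp += np.outer(_shift_vector(cfg), diseased.astype(float))
    cp[cp > cfg.detection_limit] = np.nan  # LOD censoring: undetected, not a number

    frame = pd.DataFrame(cp, index=assays, columns=sample_ids)
    if cfg.n_calibrators:
        cal = (
            CALIBRATOR_LEVEL
            + plate_offset[None, :]
            + rng_noise.normal(0.0, cfg.assay_sd / 4, (cfg.n_calibrators, n))
        )
        cal_frame = pd.DataFrame(cal, index=_calibrator_index(cfg), columns=sample_ids)
        frame = pd.concat([frame, cal_frame])
    return frame, plates


def _clean_qc(frame: pd.DataFrame, plates: pd.Series) -> AssayQC:
    """QC annotations for a clean run: one melt peak, silent negative controls."""
    melt = pd.DataFrame(1, index=frame.index, columns=frame.columns, dtype=int)
    neg = pd.Series(np.nan, index=pd.Index(pd.unique(plates), name="plate"))
    return AssayQC(melt_peaks=melt, negative_control_cp=neg)


def simulate_cohort(
    cfg: SyntheticConfig,
) -> tuple[CpMatrix, pd.DataFrame, AssayQC, pd.DataFrame]:
    """Simulate the case/control cohort.

    Returns ``(matrix, metadata, qc, truth)`` where ``matrix`` holds
    ``n_mirnas`` miRNA rows (plus calibrator rows) × ``n_disease +
    n_control + n_hemolyzed`` samples, ``truth`` lists the spiked miRNAs
    with direction and shift.  Identical seeds give identical output.
    """
    rng_base, rng_pat, rng_plate, rng_noise = _rngs(cfg.seed, 8)[:4]
    assays = _assay_index(cfg)

    n_cis = int(round(_CIS_FRACTION * cfg.n_disease))
    n_cis = min(max(n_cis, 1 if cfg.n_disease > 1 else 0), cfg.n_disease)
    groups = (
        ["CIS"] * n_cis
        + ["OSCC"] * (cfg.n_disease - n_cis)
        + ["CONTROL"] * cfg.n_control
        + ["OSCC"] * cfg.n_hemolyzed
    )
    sample_ids = pd.Index(
        [f"CIS-{i + 1:02d}" for i in range(n_cis)]
        + [f"OSCC-{i + 1:02d}" for i in range(cfg.n_disease - n_cis)]
        + [f"CTRL-{i + 1:02d}" for i in range(cfg.n_control)]
        + [f"HEM-{i + 1:02d}" for i in range(cfg.n_hemolyzed)],
        name="sample_id",
    )
    n = len(sample_ids)
    diseased = np.array([g != "CONTROL" for g in groups])
    patient_effect = rng_pat.normal(0.0, cfg.patient_sd, n)  # one sample per patient

    frame, plates = _assemble(
        cfg, assays, sample_ids, diseased, patient_effect, rng_base, rng_plate, rng_noise
    )
    meta = validate_metadata(
        pd.DataFrame(
            {
                "group": groups,
                "patient_id": [f"PT-{i + 1:03d}" for i in range(n)],
                "timepoint": "NONE",
                "hemolyzed": [s.startswith("HEM-") for s in sample_ids],
                "plate": plates.to_numpy(),
            },
            index=sample_ids,
        )
    )
    matrix = CpMatrix(frame, plates, calibrator_ids=tuple(_calibrator_index(cfg)))
    return matrix, meta, _clean_qc(frame, plates), _truth_table(cfg, assays)


def simulate_paired_cohort(
    cfg: SyntheticConfig,
) -> tuple[CpMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate matched pre/post-surgery serum pairs.

    Each of ``n_pairs`` patients contributes a PRE column (disease shifts
    applied) and a POST column (shifts removed); the two share the same
    patient random effect, so the paired contrast isolates the disease
    shift plus assay noise.  Returns ``(matrix, metadata, truth)``.
    """
    if cfg.n_pairs < 2:
        raise ConfigError("paired analysis undefined for n_pairs < 2")
    # substreams 4-7 of the same master seed: independent of the cohort draw
    rng_base, rng_pat, rng_plate, rng_noise = _rngs(cfg.seed, 8)[4:]
    assays = _assay_index(cfg)

    patients = [f"PT-{i + 1:03d}" for i in range(cfg.n_pairs)]
    sample_ids = pd.Index(
        [f"{p}-{tp}" for p in patients for tp in ("PRE", "POST")], name="sample_id"
    )
    diseased = np.array([tp == "PRE" for _ in patients for tp in ("PRE", "POST")])
    per_patient = rng_pat.normal(0.0, cfg.patient_sd, cfg.n_pairs)
    patient_effect = np.repeat(per_patient, 2)  # PRE and POST share the effect

    frame, plates = _assemble(
        cfg, assays, sample_ids, diseased, patient_effect, rng_base, rng_plate, rng_noise
    )
    groups = [("CIS" if i % 2 else "OSCC") for i in range(cfg.n_pairs)]
    meta = validate_metadata(
        pd.DataFrame(
            {
                "group": np.repeat(groups, 2),
                "patient_id": np.repeat(patients, 2),
                "timepoint": ["PRE", "POST"] * cfg.n_pairs,
                "hemolyzed": False,
                "plate": plates.to_numpy(),
            },
            index=sample_ids,
        )
    )
    matrix = CpMatrix(frame, plates, calibrator_ids=tuple(_calibrator_index(cfg)))
    return matrix, meta, _truth_table(cfg, assays)
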