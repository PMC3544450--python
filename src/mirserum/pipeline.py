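"""End-to-end orchestration of the biomarker discovery analysis.

Stage order follows the analysis design: sample QC (hemolysis) → assay
QC (censoring) → interplate calibration → global-mean normalization →
{permutation differential expression, three-group ANOVA/Tukey, paired
fold changes, clustering} → candidate intersection → ROC ranking.  A
run manifest records versions, seed, parameters and per-stage counts so
the detection/candidate accounting is reproducible from the outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .candidates import CandidateSet, select_candidates
from .cluster import ClusterTree, cluster_samples, top_variable_mirnas
from .datatypes import (
    AssayQC,
    ConfigError,
    CpMatrix,
    DISEASE_GROUPS,
    NormalizedMatrix,
)
from .differential import anova_tukey_classify, permutation_test
from .normalize import global_mean_normalize, interplate_calibrate
from .paired import PairedFoldChanges, paired_fold_changes
from .qc import DetectionSummary, detection_summary, drop_hemolyzed, filter_assays
from .roc import RocResult, rank_biomarkers, roc_table, roc_with_ci
from .simulate import SyntheticConfig, simulate_cohort, simulate_paired_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters plus the master seed and optional I/O paths."""

    # inputs: either file paths ...
    cp_matrix_path: str | None = None
    metadata_path: str | None = None
    melt_peaks_path: str | None = None
    neg_control_path: str | None = None
    paired_cp_matrix_path: str | None = None
    paired_metadata_path: str | None = None
    # ... or a synthetic study simulated in place
    simulate: SyntheticConfig | None = None
    # stage parameters
    min_detection: float = 0.6
    n_permutations: int = 10_000
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    frac_threshold: float = 0.5
    k_top: int = 50
    cluster_distance: str = "pearson"
    n_boot: int = 2000
    auc_threshold: float = 0.8
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.min_detection <= 1:
            raise ConfigError("min_detection must be in (0, 1]")
        if self.n_permutations < 1 or self.n_boot < 1:
            raise ConfigError("n_permutations and n_boot must be >= 1")
        if not 0 < self.p_threshold <= 1:
            raise ConfigError("p_threshold must be in (0, 1]")
        if self.fc_threshold <= 1:
            raise ConfigError("fc_threshold must be > 1")
        if not 0 < self.frac_threshold <= 1:
            raise ConfigError("frac_threshold must be in (0, 1]")
        if self.k_top < 1:
            raise ConfigError("k_top must be >= 1")
        if self.cluster_distance not in ("pearson", "euclidean"):
            raise ConfigError("cluster_distance must be pearson|euclidean")
        if not 0 <= self.auc_threshold < 1:
            raise ConfigError("auc_threshold must be in [0, 1)")
        has_files = self.cp_matrix_path is not None and self.metadata_path is not None
        if self.simulate is None and not has_files:
            raise ConfigError("either simulate or cp_matrix_path+metadata_path required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            for key in ("spiked_up", "spiked_down"):
                if key in sim:
                    sim[key] = tuple(tuple(x) for x in sim[key])
            if "baseline_mean_range" in sim:
                sim["baseline_mean_range"] = tuple(sim["baseline_mean_range"])
            raw["simulate"] = SyntheticConfig(**sim)
        return cls(**raw)


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    cp_matrix: CpMatrix
    metadata: pd.DataFrame
    exclusion_counts: dict
    detection: DetectionSummary
    normalized: NormalizedMatrix
    differential: pd.DataFrame
    contrast_patterns: pd.DataFrame | None
    paired: PairedFoldChanges | None
    cluster_tree: ClusterTree | None
    candidates: CandidateSet | None
    roc_results: list[RocResult]
    biomarkers: list[RocResult]
    manifest: dict
    truth: pd.DataFrame | None = None


def _stage_seeds(master: int, n: int = 4) -> list[int]:
    state = np.random.SeedSequence(master).generate_state(n)
    return [int(s % (2**31)) for s in state]


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim = config.simulate.replace(seed=_stage_seeds(config.seed)[0])
        matrix, meta, qc, truth = simulate_cohort(sim)
        paired_matrix, paired_meta, _ = simulate_paired_cohort(sim)
        return matrix, meta, qc, paired_matrix, paired_meta, truth
    meta = io.read_metadata(config.metadata_path)
    plates = meta["plate"] if "plate" in meta.columns else None
    matrix = io.read_cp_matrix(config.cp_matrix_path, plates=plates)
    if config.melt_peaks_path and config.neg_control_path:
        qc = io.read_assay_qc(config.melt_peaks_path, config.neg_control_path)
    else:
        qc = AssayQC(
            melt_peaks=pd.DataFrame(1, index=matrix.values.index, columns=matrix.sample_ids),
            negative_control_cp=pd.Series(np.nan, index=pd.unique(matrix.plates)),
        )
    paired_matrix = paired_meta = None
    if config.paired_cp_matrix_path and config.paired_metadata_path:
        paired_meta = io.read_metadata(config.paired_metadata_path)
        pplates = paired_meta["plate"] if "plate" in paired_meta.columns else None
        paired_matrix = io.read_cp_matrix(config.paired_cp_matrix_path, plates=pplates)
    return matrix, meta, qc, paired_matrix, paired_meta, None


def _normalize_stage(matrix: CpMatrix, qc: AssayQC, meta, counts: dict):
    matrix, meta, n_hem = drop_hemolyzed(matrix, meta)
    matrix, excl = filter_assays(matrix, qc)
    counts["n_hemolyzed_removed"] = n_hem
    counts["exclusions"] = excl
    if matrix.calibrator_ids:
        matrix, offsets = interplate_calibrate(matrix)
    else:
        offsets = None
        logger.info("no calibrator assays; skipping interplate calibration")
    return matrix, meta, global_mean_normalize(matrix, plate_offsets=offsets), excl


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; optionally write all outputs to ``outdir``.

    Deterministic: identical configuration and inputs give identical
    outputs, including the permutation and bootstrap stages, which draw
    their seeds from the master seed.
    """
    seeds = _stage_seeds(config.seed)
    counts: dict = {}
    matrix, meta, qc, paired_matrix, paired_meta, truth = _load_inputs(config)
    counts["n_samples_in"] = len(matrix.sample_ids)
    counts["n_mirnas"] = len(matrix.mirna_ids)

    matrix, meta, norm, _ = _normalize_stage(matrix, qc, meta, counts)
    counts["n_samples_analyzed"] = len(matrix.sample_ids)
    detection = detection_summary(matrix, meta)
    counts["n_detected_ge1"] = detection.n_detected_ge1
    counts["n_detected_all"] = detection.n_detected_all

    diff = permutation_test(
        norm,
        meta,
        n_permutations=config.n_permutations,
        seed=seeds[1],
        min_detection=config.min_detection,
    )
    counts["n_gated"] = len(diff)
    sig = diff["p_adj"] < config.p_threshold
    counts["n_significant_up"] = int((sig & (diff["direction"] == "UP")).sum())
    counts["n_significant_down"] = int((sig & (diff["direction"] == "DOWN")).sum())

    patterns = None
    if set(DISEASE_GROUPS) <= set(meta["group"].unique()):
        patterns = anova_tukey_classify(norm, meta, min_detection=config.min_detection)
        counts["n_anova_patterns"] = (
            patterns["pattern"].value_counts().to_dict() if len(patterns) else {}
        )

    paired = cluster_tree = cands = None
    roc_results: list[RocResult] = []
    biomarkers: list[RocResult] = []
    if paired_matrix is not None:
        paired_qc = AssayQC(
            melt_peaks=pd.DataFrame(
                1, index=paired_matrix.values.index, columns=paired_matrix.sample_ids
            ),
            negative_control_cp=pd.Series(np.nan, index=pd.unique(paired_matrix.plates)),
        )
        paired_counts: dict = {}
        paired_matrix, paired_meta, paired_norm, _ = _normalize_stage(
            paired_matrix, paired_qc, paired_meta, paired_counts
        )
        counts["paired"] = paired_counts
        counts["n_pairs"] = len(paired_meta[paired_meta["timepoint"] == "PRE"])

        paired = paired_fold_changes(paired_norm, paired_meta, fc_threshold=config.fc_threshold)
        reduced = top_variable_mirnas(paired_norm, k=config.k_top)
        cluster_tree = cluster_samples(reduced, distance=config.cluster_distance)

        cands = select_candidates(
            diff,
            paired,
            p_threshold=config.p_threshold,
            fc_threshold=config.fc_threshold,
            frac_threshold=config.frac_threshold,
        )
        counts["n_candidates_up"] = len(cands.upregulated)
        counts["n_candidates_down"] = len(cands.downregulated)

        labels = meta.loc[matrix.sample_ids, "group"].isin(DISEASE_GROUPS).to_numpy()
        for i, mirna in enumerate(cands.table.index):
            roc_results.append(
                roc_with_ci(
                    norm.values.loc[mirna],
                    labels,
                    n_boot=config.n_boot,
                    seed=(seeds[2] + i) % (2**31),
                    mirna_id=mirna,
                )
            )
        biomarkers = rank_biomarkers(roc_results, auc_threshold=config.auc_threshold)
        counts["n_biomarkers"] = len(biomarkers)

    manifest = {
        "package": "mirserum",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "parameters": {
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(config)
            if f.name not in ("simulate",) and not f.name.endswith("_path")
        },
        "simulated": config.simulate is not None,
        "counts": counts,
    }
    result = PipelineResult(
        cp_matrix=matrix,
        metadata=meta,
        exclusion_counts=counts.get("exclusions", {}),
        detection=detection,
        normalized=norm,
        differential=diff,
        contrast_patterns=patterns,
        paired=paired,
        cluster_tree=cluster_tree,
        candidates=cands,
        roc_results=roc_results,
        biomarkers=biomarkers,
        manifest=manifest,
        truth=truth,
    )
    if config.outdir:
        _write_outputs(result, Path(config.outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_cp_matrix(result.cp_matrix, outdir / "cp_filtered.tsv")
    io.write_metadata(result.metadata, outdir / "metadata.tsv")
    io.write_normalized_matrix(result.normalized, outdir / "dcp_normalized.tsv")
    io.write_table(result.differential, outdir / "differential.tsv")
    if result.contrast_patterns is not None:
        io.write_table(result.contrast_patterns, outdir / "contrast_patterns.tsv")
    if result.paired is not None:
        table = result.paired.log2fc.copy()
        table["n_evaluable"] = result.paired.n_evaluable
        table["fraction_up"] = result.paired.fraction_up
        table["fraction_down"] = result.paired.fraction_down
        io.write_table(table.rename_axis("mirna_id"), outdir / "paired_fold_changes.tsv")
    if result.candidates is not None:
        io.write_table(result.candidates.table, outdir / "candidates.tsv")
    if result.cluster_tree is not None:
        (outdir / "cluster_tree.nwk").write_text(result.cluster_tree.to_newick() + "\n")
    if result.roc_results:
        io.write_table(roc_table(result.roc_results), outdir / "roc_summary.tsv")
    if result.truth is not None:
        result.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    io.write_manifest(result.manifest, outdir / "manifest.json")
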