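"""Matched pre/post-surgery fold-change analysis.

For each patient with serum drawn before and after tumor resection, the
per-miRNA log2 fold change is

    log2 fc(m, patient) = ΔCp(m, post) − ΔCp(m, pre)

Because lower ΔCp means more abundant, a *positive* log2 fc (linear
fc = 2^log2fc > 1) means the miRNA was more abundant **pre-surgery**,
i.e. in the disease state; removing the tumor removed its source.  One
cycle of ΔCp difference is exactly a 2-fold abundance change.

A pair in which either member is undetected is MISSING for that miRNA
and excluded from the recurrence fractions, whose denominator is the
number of evaluable pairs.  The recurrence criterion asks whether the
fold change exceeds a threshold (default 2-fold, strict) in at least a
given fraction of pairs (default 50%, inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MetadataError, NormalizedMatrix, validate_metadata


@dataclass
class PairedFoldChanges:
    """Per-pair log2 fold changes and recurrence fractions.

    ``log2fc`` is a miRNA × patient DataFrame (NaN = pair not evaluable);
    ``fraction_up`` / ``fraction_down`` are the fractions of evaluable
    pairs with linear fold change strictly above ``fc_threshold`` /
    strictly below ``1 / fc_threshold``.
    """

    log2fc: pd.DataFrame
    n_evaluable: pd.Series
    fraction_up: pd.Series
    fraction_down: pd.Series
    fc_threshold: float

    def fractions_at(self, fc_threshold: float) -> tuple[pd.Series, pd.Series]:
        """Recompute (fraction_up, fraction_down) at another fold threshold."""
        return _fractions(self.log2fc, fc_threshold)


def _fractions(log2fc: pd.DataFrame, fc_threshold: float) -> tuple[pd.Series, pd.Series]:
    cut = np.log2(fc_threshold)
    n_eval = log2fc.notna().sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN fraction
        up = (log2fc > cut).sum(axis=1) / n_eval
        down = (log2fc < -cut).sum(axis=1) / n_eval
    return up, down


def match_pairs(meta: pd.DataFrame) -> pd.DataFrame:
    """Return a patient-indexed table with ``pre`` / ``post`` sample ids."""
    meta = validate_metadata(meta)
    pre = meta[meta["timepoint"] == "PRE"]
    post = meta[meta["timepoint"] == "POST"]
    post_by_patient = pd.Series(post.index, index=post["patient_id"])
    unmatched = set(pre["patient_id"]) - set(post["patient_id"])
    if unmatched:
        raise MetadataError(f"PRE sample(s) without a POST mate for patient(s): {sorted(unmatched)}")
    pairs = pd.DataFrame(
        {"pre": pre.index, "post": pre["patient_id"].map(post_by_patient).to_numpy()},
        index=pd.Index(pre["patient_id"], name="patient_id"),
    )
    if len(pairs) < 2:
        raise MetadataError(f"paired analysis requires >= 2 complete pairs, found {len(pairs)}")
    return pairs


def paired_fold_changes(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    fc_threshold: float = 2.0,
    exponent: str = "post_minus_pre",
) -> PairedFoldChanges:
    """Compute per-pair log2 fold changes ΔCp(post) − ΔCp(pre).

    The metadata must define at least two complete (PRE, POST) pairs
    linked by ``patient_id``; a PRE sample without its mate is an error.
    ``exponent="pre_minus_post"`` flips the sign for literal comparison
    with tools that print 2^(preΔCp − postΔCp); under the lower-ΔCp-is-
    more-abundant convention that order makes fc > 1 mean *less*
    abundant in disease, so the default keeps post − pre.
    """
    if exponent not in ("post_minus_pre", "pre_minus_post"):
        raise ValueError(f"unknown exponent order {exponent!r}")
    pairs = match_pairs(meta)
    values = norm.values
    pre = values[pairs["pre"]].to_numpy()
    post = values[pairs["post"]].to_numpy()
    diff = post - pre if exponent == "post_minus_pre" else pre - post
    log2fc = pd.DataFrame(diff, index=values.index, columns=pairs.index)
    up, down = _fractions(log2fc, fc_threshold)
    return PairedFoldChanges(
        log2fc=log2fc,
        n_evaluable=log2fc.notna().sum(axis=1),
        fraction_up=up,
        fraction_down=down,
        fc_threshold=fc_threshold,
    )


def recurrence_filter(
    pfc: PairedFoldChanges, fc_threshold: float = 2.0, frac_threshold: float = 0.5
) -> pd.DataFrame:
    """Flag miRNAs recurrently changed across pairs.

    ``recurrently_up`` ⇔ fraction of evaluable pairs with linear fold
    change > ``fc_threshold`` is ≥ ``frac_threshold`` (boundary
    inclusive); symmetrically for ``recurrently_down``.  At
    ``frac_threshold == 0.5`` a miRNA can carry both flags (fractions
    exactly ½ each); such rows are marked ``ambiguous`` and warned about.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    if not 0 < frac_threshold <= 1:
        raise ValueError("frac_threshold must be in (0, 1]")
    up, down = pfc.fractions_at(fc_threshold)
    flags = pd.DataFrame(
        {
            "recurrently_up": (up >= frac_threshold).fillna(False),
            "recurrently_down": (down >= frac_threshold).fillna(False),
            "fraction_up": up,
            "fraction_down": down,
            "n_evaluable": pfc.n_evaluable,
        }
    )
    flags["ambiguous"] = flags["recurrently_up"] & flags["recurrently_down"]
    if flags["ambiguous"].any():
        warnings.warn(
            f"{int(flags['ambiguous'].sum())} miRNA(s) recurrently up AND down at the "
            f"{frac_threshold:.0%} boundary"
        )
    return flags
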