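"""Candidate intersection and cross-compartment concordance.

A serum biomarker candidate must clear two independent hurdles with a
consistent direction: (1) BH-adjusted permutation p below threshold in
the case/control cohort, and (2) recurrent ≥-threshold fold change in
the matched pre/post-surgery pairs.  An upregulated candidate must be
more abundant both in disease sera (statistic < 0) and pre-surgery
(recurrently_up); symmetrically for downregulated ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DataError
from .paired import PairedFoldChanges, recurrence_filter

logger = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    """Candidates passing both criteria, with the parameters used."""

    table: pd.DataFrame
    p_threshold: float
    fc_threshold: float
    frac_threshold: float

    @property
    def upregulated(self) -> pd.DataFrame:
        return self.table[self.table["direction"] == "UP"]

    @property
    def downregulated(self) -> pd.DataFrame:
        return self.table[self.table["direction"] == "DOWN"]

    def __len__(self) -> int:
        return len(self.table)


def select_candidates(
    diff: pd.DataFrame,
    pfc: PairedFoldChanges,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    frac_threshold: float = 0.5,
) -> CandidateSet:
    """Intersect cohort-level and paired criteria with direction concordance.

    ``diff`` is the output of :func:`mirserum.differential.permutation_test`.
    A miRNA is a candidate iff ``p_adj < p_threshold`` and its direction
    agrees with the recurrence flag (UP with ``recurrently_up``, DOWN
    with ``recurrently_down``).  miRNAs present in only one input are
    logged and skipped.  The table is sorted by adjusted p ascending.
    """
    flags = recurrence_filter(pfc, fc_threshold=fc_threshold, frac_threshold=frac_threshold)
    shared = diff.index.intersection(flags.index)
    only = len(diff.index.symmetric_difference(flags.index))
    if only:
        logger.info("%d miRNA(s) present in only one analysis; not candidates", only)

    d = diff.loc[shared]
    f = flags.loc[shared]
    concordant = ((d["direction"] == "UP") & f["recurrently_up"]) | (
        (d["direction"] == "DOWN") & f["recurrently_down"]
    )
    keep = (d["p_adj"] < p_threshold) & concordant
    table = d.loc[keep, ["statistic", "p_raw", "p_adj", "direction"]].copy()
    table["recurrence_fraction"] = np.where(
        table["direction"] == "UP",
        f.loc[keep, "fraction_up"],
        f.loc[keep, "fraction_down"],
    )
    table = table.sort_values(["p_adj", "p_raw"]).rename_axis("mirna_id")
    return CandidateSet(
        table=table,
        p_threshold=p_threshold,
        fc_threshold=fc_threshold,
        frac_threshold=frac_threshold,
    )


def concordance_overlap(set_a, set_b) -> dict[str, int]:
    """Count direction-concordant overlap between two (miRNA, direction) sets.

    Accepts iterables of ``(mirna_id, direction)`` with direction in
    {UP, DOWN}.  Returns counts ``both_up``, ``both_down``,
    ``discordant``, ``a_only``, ``b_only``; the counts partition the
    union of the two sets.
    """

    def _as_map(pairs, name):
        out = {}
        for mirna, direction in pairs:
            if direction not in ("UP", "DOWN"):
                raise DataError(f"direction {direction!r} for {mirna!r} not in {{UP, DOWN}}")
            if mirna in out:
                raise DataError(f"duplicate miRNA {mirna!r} in set {name}")
            out[mirna] = direction
        return out

    a = _as_map(set_a, "A")
    b = _as_map(set_b, "B")
    shared = a.keys() & b.keys()
    return {
        "both_up": sum(1 for m in shared if a[m] == b[m] == "UP"),
        "both_down": sum(1 for m in shared if a[m] == b[m] == "DOWN"),
        "discordant": sum(1 for m in shared if a[m] != b[m]),
        "a_only": len(a.keys() - b.keys()),
        "b_only": len(b.keys() - a.keys()),
    }
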