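"""Average-linkage hierarchical clustering of samples.

Samples are clustered on the ``k`` most variable miRNAs (highest standard
deviation of detected ΔCp, default 50), using pairwise-complete
dissimilarities: each sample pair is compared only on miRNAs detected in
both, requiring at least three shared values.  The default metric is
Pearson correlation distance, 1 − r, which is invariant to per-sample
affine rescaling; Euclidean distance is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .datatypes import DataError, NormalizedMatrix

MIN_SHARED = 3  # minimum mutually detected miRNAs per sample pair


def top_variable_mirnas(norm: NormalizedMatrix, k: int = 50) -> NormalizedMatrix:
    """Keep the ``k`` miRNAs with the largest SD of detected ΔCp.

    Only miRNAs with at least two detected values are eligible (SD is
    undefined otherwise).  Ties at the cutoff are broken by miRNA id in
    lexicographic order so the subset is deterministic.
    """
    values = norm.values
    eligible = values.notna().sum(axis=1) >= 2
    sd = values[eligible].std(axis=1, ddof=1, skipna=True)
    if len(sd) < k:
        warnings.warn(f"only {len(sd)} miRNA(s) eligible for top-{k} selection; using all")
        k = len(sd)
    order = sorted(sd.index, key=lambda m: (-sd[m], m))
    chosen = pd.Index(order[:k])
    keep = [m for m in values.index if m in set(chosen)]  # preserve row order
    out = norm.copy()
    out.values = out.values.loc[keep]
    return out


@dataclass
class ClusterTree:
    """Binary merge tree over samples (scipy linkage encoding)."""

    linkage: np.ndarray
    labels: list[str]
    distance: str
    linkage_method: str
    k_mirnas: int

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.dendrogram(self.linkage, no_plot=True)["leaves"]
        return [self.labels[i] for i in order]

    def cut(self, n_clusters: int) -> pd.Series:
        """Cluster membership (1..n_clusters) per sample."""
        assign = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        root = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            children = ",".join(fmt(c, node.dist) for c in (node.left, node.right))
            return f"({children}):{length:.6g}"

        children = ",".join(fmt(c, root.dist) for c in (root.left, root.right))
        return f"({children});"


def _pairwise_complete_distance(values: pd.DataFrame, distance: str) -> np.ndarray:
    """Condensed distance vector over samples with pairwise-complete cells."""
    arr = values.to_numpy()
    det = ~np.isnan(arr)
    n = arr.shape[1]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = det[:, i] & det[:, j]
            if shared.sum() < MIN_SHARED:
                raise DataError(
                    f"samples {values.columns[i]!r} and {values.columns[j]!r} share only "
                    f"{int(shared.sum())} detected miRNA(s) (< {MIN_SHARED})"
                )
            x, y = arr[shared, i], arr[shared, j]
            if distance == "euclidean":
                out.append(float(np.sqrt(np.sum((x - y) ** 2))))
            else:  # pearson
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    # degenerate constant profile: identical -> 0, else maximal
                    out.append(0.0 if np.allclose(x, y) else 2.0)
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                    out.append(1.0 - r)
    return np.asarray(out)


def cluster_samples(
    reduced: NormalizedMatrix,
    distance: str = "pearson",
    linkage_method: str = "average",
) -> ClusterTree:
    """Average-linkage hierarchical clustering of samples.

    Deterministic: the tree depends only on the pairwise distances, not
    on sample input order (up to leaf relabeling).
    """
    if distance not in ("pearson", "euclidean"):
        raise ValueError(f"unknown distance {distance!r}")
    values = reduced.values
    if values.shape[1] < 2:
        raise DataError("clustering requires at least 2 samples")
    condensed = _pairwise_complete_distance(values, distance)
    linked = hierarchy.linkage(condensed, method=linkage_method)
    return ClusterTree(
        linkage=linked,
        labels=list(values.columns),
        distance=distance,
        linkage_method=linkage_method,
        k_mirnas=values.shape[0],
    )
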