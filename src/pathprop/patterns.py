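"""Disruption patterns: Z-scores, complete-linkage clustering, co-disruption.

Clustering is a deterministic agglomerative implementation (complete
linkage, correlation or euclidean distance) with lexicographic
tie-breaking, so reordered inputs and repeated runs give byte-identical
output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import PathwayActivityMatrix

log = logging.getLogger(__name__)


def zscore_by_cancer(matrix: PathwayActivityMatrix) -> PathwayActivityMatrix:
    """Z-transform each cancer row: (x - mean) / sd with the n-1 denominator.

    Missing entries stay missing; a zero-variance row maps to all zeros
    with a warning; rows with fewer than two observed values are an error.
    """
    scores = matrix.scores.copy().astype(float)
    for cancer in scores.index:
        row = scores.loc[cancer]
        observed = row.dropna()
        if len(observed) < 2:
            raise ValueError(f"cancer {cancer!r} has fewer than 2 pathway scores")
        sd = observed.std(ddof=1)
        if sd == 0:
            log.warning("cancer %r: zero-variance row mapped to zeros", cancer)
            scores.loc[cancer, observed.index] = 0.0
        else:
            scores.loc[cancer, observed.index] = (observed - observed.mean()) / sd
    return PathwayActivityMatrix(
        scores=scores, coverage=matrix.coverage, collections=matrix.collections,
        p_values=matrix.p_values, q_values=matrix.q_values,
    )


# ---------------------------------------------------------------------------
# deterministic complete-linkage agglomeration


@dataclass
class ClusterTree:
    """Binary merge tree; leaves carry labels, internal nodes carry heights."""

    label: str | None = None
    left: "ClusterTree | None" = None
    right: "ClusterTree | None" = None
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.left.leaves() + self.right.leaves()

    def to_newick(self) -> str:
        def render(node: "ClusterTree", parent_height: float) -> str:
            branch = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                return f"{node.label}:{branch:.6g}"
            inner = ",".join(
                render(child, node.height) for child in (node.left, node.right)
            )
            return f"({inner}):{branch:.6g}"

        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(
            render(child, self.height) for child in (self.left, self.right)
        )
        return f"({inner});"


@dataclass
class ClusteringResult:
    row_order: list[str] | None
    column_order: list[str] | None
    row_tree: ClusterTree | None
    column_tree: ClusterTree | None
    distance_label: str
    linkage_label: str = "complete"


def _distance_matrix(data: np.ndarray, distance: str) -> np.ndarray:
    if distance == "euclidean":
        diff = data[:, None, :] - data[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=2))
    elif distance == "correlation":
        sd = data.std(axis=1)
        if (sd == 0).any():
            raise ValueError("zero-variance profile; correlation distance undefined")
        corr = np.corrcoef(data)
        D = np.clip(1.0 - corr, 0.0, 2.0)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return (D + D.T) / 2.0  # force exact symmetry (BLAS sums differ by orientation)


def _agglomerate(data: np.ndarray, labels: list[str], distance: str) -> ClusterTree:
    """Complete-linkage agglomeration with deterministic tie-breaking.

    Among pairs at the minimal distance, the pair whose sorted leaf-label
    tuples compare smallest is merged first; within a merge the cluster
    with the smaller key becomes the left child.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    D = _distance_matrix(data, distance)
    np.fill_diagonal(D, np.inf)
    trees = [ClusterTree(label=lab) for lab in labels]
    keys = [(lab,) for lab in labels]  # sorted leaf labels per cluster
    active = [True] * n
    for _ in range(n - 1):
        dmin = D.min()
        candidates = np.argwhere(np.isclose(D, dmin, rtol=0, atol=0))
        best = None
        for a, b in candidates:
            i, j = (int(a), int(b)) if a < b else (int(b), int(a))
            if i == j or not (active[i] and active[j]):
                continue
            key = tuple(sorted((keys[i], keys[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        if best is None:  # defensive: cannot happen with a symmetric finite D
            raise RuntimeError("no mergeable pair found")
        _, i, j = best
        left, right = (i, j) if keys[i] <= keys[j] else (j, i)
        merged = ClusterTree(
            left=trees[left], right=trees[right], height=float(dmin)
        )
        # complete linkage: distance to the union is the max of the parts
        new_row = np.maximum(D[i], D[j])
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf
        active[j] = False
        trees[i] = merged
        keys[i] = tuple(sorted(keys[i] + keys[j]))
    return trees[i]


def hierarchical_cluster(
    matrix: PathwayActivityMatrix | pd.DataFrame,
    axis: str = "both",
    linkage: str = "complete",
    distance: str = "correlation",
) -> ClusteringResult:
    """Two-way agglomerative clustering of the activity matrix.

    Columns containing missing values (flagged pathways) must be filtered
    beforehand; rows = cancers, columns = pathways.
    """
    if linkage != "complete":
        raise ValueError("only complete linkage is supported")
    if axis not in ("rows", "columns", "both"):
        raise ValueError(f"unknown axis {axis!r}")
    frame = matrix.scores if isinstance(matrix, PathwayActivityMatrix) else matrix
    if frame.isna().any().any():
        raise ValueError("matrix contains missing values; filter flagged pathways first")
    row_tree = column_tree = None
    row_order = column_order = None
    if axis in ("rows", "both"):
        row_tree = _agglomerate(
            frame.to_numpy(dtype=float), [str(x) for x in frame.index], distance
        )
        row_order = row_tree.leaves()
    if axis in ("columns", "both"):
        column_tree = _agglomerate(
            frame.to_numpy(dtype=float).T, [str(x) for x in frame.columns], distance
        )
        column_order = column_tree.leaves()
    return ClusteringResult(
        row_order=row_order, column_order=column_order,
        row_tree=row_tree, column_tree=column_tree,
        distance_label=distance, linkage_label=linkage,
    )


def codisruption_correlation(
    matrix: PathwayActivityMatrix, top_n: int
) -> pd.DataFrame:
    """Pearson correlation of pathway activity profiles across cancers.

    Restricted to the ``top_n`` pathways by mean activity (ties broken by
    name). Zero-variance profiles give missing off-diagonal entries.
    """
    means = matrix.scores.mean(axis=0, skipna=True).dropna()
    if top_n > len(means):
        raise ValueError(
            f"top_n={top_n} exceeds the {len(means)} rankable pathways"
        )
    ranked = sorted(means.index, key=lambda n: (-means[n], n))[:top_n]
    data = matrix.scores[ranked].to_numpy(dtype=float).T  # pathways x cancers
    sd = np.nanstd(data, axis=1)
    corr = np.full((top_n, top_n), np.nan)
    valid = sd > 0
    if valid.any():
        sub = np.corrcoef(data[valid])
        corr[np.ix_(valid, valid)] = sub
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=ranked, columns=ranked)
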