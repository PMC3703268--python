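"""Permutation significance, BH adjustment, and pathway selection.

Null pathway scores come from shuffling the initial activity scores over
network nodes (with re-propagation) and/or relabeling pathway
memberships; empirical p-values use the standard +1 correction and are
BH-adjusted within each (cancer, collection) family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .graph import GeneNetwork, NormalizedAdjacency
from .propagation import LinearPropagator, PropagationConfig, propagate_closed_form
from .scoring import PathwayActivityMatrix, PathwayCollection, member_indices
from .seeds import ActivityVector

DEFAULT_FDR_CUTOFFS: dict[str, float] = {"biocarta": 0.005, "default": 0.10}


@dataclass
class PermutationConfig:
    n_permutations: int = 10_000
    mode: str = "both"  # {"membership", "scores", "both"}
    rng_seed: int = 0
    fdr_cutoffs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FDR_CUTOFFS)
    )

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if self.mode not in ("membership", "scores", "both"):
            raise ConfigurationError(f"unknown permutation mode {self.mode!r}")
        for label, cutoff in self.fdr_cutoffs.items():
            if not 0.0 < cutoff < 1.0:
                raise ConfigurationError(
                    f"FDR cutoff for {label!r} must be in (0, 1), got {cutoff}"
                )


@dataclass
class SelectionCriteria:
    per_cancer_top_fraction: float = 0.20
    common_top_fraction: float = 0.10
    min_cancer_types: int = 10
    subnetwork_top_fraction: float = 0.05

    def __post_init__(self) -> None:
        for frac in (
            self.per_cancer_top_fraction,
            self.common_top_fraction,
            self.subnetwork_top_fraction,
        ):
            if not 0.0 < frac <= 1.0:
                raise ConfigurationError(f"top fraction must be in (0, 1], got {frac}")
        if self.min_cancer_types < 1:
            raise ConfigurationError("min_cancer_types must be >= 1")


def resolve_cutoff(fdr_cutoffs: Mapping[str, float], collection_label: str) -> float:
    """Collection-specific FDR cutoff with case-insensitive lookup."""
    label = collection_label.lower()
    if label in fdr_cutoffs:
        return fdr_cutoffs[label]
    return fdr_cutoffs.get("default", DEFAULT_FDR_CUTOFFS["default"])


def permutation_null(
    net: GeneNetwork,
    gbar: NormalizedAdjacency,
    g_initial: ActivityVector,
    pathways: PathwayCollection,
    cfg: PermutationConfig,
    prop_cfg: PropagationConfig,
) -> tuple[np.ndarray, list[str]]:
    """Null pathway-score samples, shape (n_permutations, n_pathways).

    ``scores``/``both`` modes shuffle the initial vector over nodes and
    re-propagate each round; ``membership``/``both`` modes relabel the
    network genes with a fresh uniform permutation, which hands every
    pathway a uniform random in-network member set of its own size.
    Pathways without in-network members get NaN columns. Deterministic
    for a given ``rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n = net.n_nodes
    idx = member_indices(pathways, net)
    names = pathways.names
    sizes = np.array([len(idx[name]) for name in names], dtype=np.intp)
    nonempty = np.flatnonzero(sizes > 0)
    concat = np.concatenate([idx[names[j]] for j in nonempty]) if len(nonempty) else np.empty(0, dtype=np.intp)
    offsets = np.zeros(len(nonempty), dtype=np.intp)
    if len(nonempty):
        offsets[1:] = np.cumsum(sizes[nonempty])[:-1]

    shuffle_scores = cfg.mode in ("scores", "both")
    shuffle_members = cfg.mode in ("membership", "both")
    solver = LinearPropagator(gbar, prop_cfg.alpha)
    gtilde_fixed = solver.solve(g_initial.scores) if not shuffle_scores else None

    nulls = np.full((cfg.n_permutations, len(names)), np.nan)
    for b in range(cfg.n_permutations):
        if shuffle_scores:
            gt = solver.solve(g_initial.scores[rng.permutation(n)])
        else:
            gt = gtilde_fixed
        if shuffle_members:
            relabel = rng.permutation(n)
            vals = gt[relabel[concat]]
        else:
            vals = gt[concat]
        if len(nonempty):
            sums = np.add.reduceat(vals, offsets)
            nulls[b, nonempty] = sums / sizes[nonempty]
    return nulls, names


def empirical_pvalues(
    observed: pd.Series, nulls: np.ndarray, names: Sequence[str] | None = None
) -> pd.Series:
    """p = (1 + #{null >= observed}) / (B + 1), per pathway.

    NaN observed scores (flagged pathways) yield NaN p-values; a pathway
    whose null column is entirely NaN while its score is defined is an
    error.
    """
    if names is not None:
        nulls = pd.DataFrame(nulls, columns=list(names))[list(observed.index)].to_numpy()
    if nulls.ndim != 2 or nulls.shape[1] != len(observed):
        raise ValueError("null sample shape does not match observed scores")
    B = nulls.shape[0]
    obs = observed.to_numpy(dtype=float)
    p = np.full(len(obs), np.nan)
    for j, s in enumerate(obs):
        if math.isnan(s):
            continue
        col = nulls[:, j]
        if np.isnan(col).all():
            raise ValueError(f"missing null samples for pathway {observed.index[j]!r}")
        p[j] = (1.0 + np.sum(col >= s)) / (B + 1.0)
    return pd.Series(p, index=observed.index)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved.

    NaN entries pass through and do not count toward the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    flat = p.ravel()
    mask = ~np.isnan(flat)
    vals = flat[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = vals.size
    q = np.full(flat.shape, np.nan)
    if n:
        order = np.argsort(vals, kind="stable")
        ranked = vals[order] * n / np.arange(1, n + 1)
        adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
        adjusted = np.minimum(adjusted, 1.0)
        out = np.empty(n)
        out[order] = adjusted
        q[mask] = out
    return q.reshape(p.shape)


def attach_significance(
    matrix: PathwayActivityMatrix,
    p_values: pd.DataFrame,
) -> PathwayActivityMatrix:
    """Return a copy of the matrix with p-values and per-(cancer, collection) BH q-values."""
    pv = p_values.reindex(index=matrix.scores.index, columns=matrix.scores.columns)
    qv = pd.DataFrame(np.nan, index=pv.index, columns=pv.columns)
    groups = _collection_groups(matrix)
    for cancer in pv.index:
        for _, cols in groups.items():
            qv.loc[cancer, cols] = bh_adjust(pv.loc[cancer, cols].to_numpy())
    return PathwayActivityMatrix(
        scores=matrix.scores, coverage=matrix.coverage,
        collections=matrix.collections, p_values=pv, q_values=qv,
    )


def _collection_groups(matrix: PathwayActivityMatrix) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for name in matrix.pathway_names:
        groups.setdefault(matrix.collection_of(name), []).append(name)
    return groups


def top_fraction_count(n_ranked: int, fraction: float) -> int:
    return int(math.ceil(fraction * n_ranked))


def _qualifying(
    matrix: PathwayActivityMatrix,
    top_fraction: float,
    fdr_cutoffs: Mapping[str, float],
) -> pd.DataFrame:
    """Boolean cancers x pathways frame: significant AND within top fraction.

    Ranking is by descending score within each collection family, ties
    broken by pathway name for determinism.
    """
    if matrix.q_values is None:
        raise ValueError("matrix carries no q-values; run significance first")
    out = pd.DataFrame(
        False, index=matrix.scores.index, columns=matrix.scores.columns
    )
    groups = _collection_groups(matrix)
    for cancer in matrix.scores.index:
        for label, cols in groups.items():
            cutoff = resolve_cutoff(fdr_cutoffs, label)
            scores = matrix.scores.loc[cancer, cols].dropna()
            if scores.empty:
                continue
            k = top_fraction_count(len(scores), top_fraction)
            ranked = sorted(scores.index, key=lambda n: (-scores[n], n))
            top = set(ranked[:k])
            qrow = matrix.q_values.loc[cancer]
            for name in scores.index:
                q = qrow[name]
                out.loc[cancer, name] = (
                    name in top and not math.isnan(q) and q <= cutoff
                )
    return out


def select_per_cancer(
    matrix: PathwayActivityMatrix,
    criteria: SelectionCriteria,
    fdr_cutoffs: Mapping[str, float] | None = None,
) -> dict[str, list[str]]:
    """Disrupted pathways per cancer: significant q AND top-fraction rank."""
    cutoffs = fdr_cutoffs if fdr_cutoffs is not None else DEFAULT_FDR_CUTOFFS
    qual = _qualifying(matrix, criteria.per_cancer_top_fraction, cutoffs)
    return {
        cancer: sorted(qual.columns[qual.loc[cancer]])
        for cancer in qual.index
    }


def select_common(
    matrix: PathwayActivityMatrix,
    criteria: SelectionCriteria,
    fdr_cutoffs: Mapping[str, float] | None = None,
    top_fraction: float | None = None,
) -> pd.DataFrame:
    """Commonly disrupted pathways: significant + top-fraction in >= min cancers.

    Returns a frame (pathway, n_cancers, cancers, mean_score) sorted by
    recurrence count, then mean score, then name.
    """
    cutoffs = fdr_cutoffs if fdr_cutoffs is not None else DEFAULT_FDR_CUTOFFS
    frac = top_fraction if top_fraction is not None else criteria.common_top_fraction
    qual = _qualifying(matrix, frac, cutoffs)
    rows = []
    for name in qual.columns:
        cancers = sorted(qual.index[qual[name]])
        if len(cancers) >= criteria.min_cancer_types:
            rows.append({
                "pathway": name,
                "n_cancers": len(cancers),
                "cancers": ",".join(cancers),
                "mean_score": float(matrix.scores[name].mean(skipna=True)),
            })
    frame = pd.DataFrame(rows, columns=["pathway", "n_cancers", "cancers", "mean_score"])
    if not frame.empty:
        frame = frame.sort_values(
            ["n_cancers", "mean_score", "pathway"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return frame


def select_specific(
    matrix: PathwayActivityMatrix,
    criteria: SelectionCriteria,
    fdr_cutoffs: Mapping[str, float] | None = None,
    max_cancer_types: int = 2,
) -> dict[str, list[str]]:
    """Cancer-type-specific pathways, keyed by each cancer where they qualify."""
    cutoffs = fdr_cutoffs if fdr_cutoffs is not None else DEFAULT_FDR_CUTOFFS
    qual = _qualifying(matrix, criteria.common_top_fraction, cutoffs)
    out: dict[str, list[str]] = {cancer: [] for cancer in qual.index}
    for name in qual.columns:
        cancers = sorted(qual.index[qual[name]])
        if 1 <= len(cancers) <= max_cancer_types:
            for cancer in cancers:
                out[cancer].append(name)
    return {c: sorted(v) for c, v in out.items() if v}
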