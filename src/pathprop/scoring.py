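"""Pathway collections (GMT) and pathway activity scoring.

A pathway's activity in one cancer type is the mean propagated score of
its member genes; per-cancer score vectors assemble into a cancer x
pathway matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError
from .graph import GeneNetwork, normalize_symbol
from .seeds import ActivityVector

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Pathway:
    name: str
    description: str
    members: tuple[str, ...]  # sorted, unique, uppercase

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass
class PathwayCollection:
    pathways: list[Pathway]
    source_label: str = "default"

    def __post_init__(self) -> None:
        names = [p.name for p in self.pathways]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ParseError(f"duplicate pathway name(s): {', '.join(dupes)}")
        for p in self.pathways:
            if not p.members:
                raise ParseError(f"pathway {p.name!r} has no members")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pathways]

    def __getitem__(self, name: str) -> Pathway:
        for p in self.pathways:
            if p.name == name:
                return p
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.pathways)

    def member_union(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways:
            out.update(p.members)
        return out


def make_pathway(name: str, description: str, members: Iterable[str]) -> Pathway:
    uniq = sorted({normalize_symbol(m) for m in members if m.strip()})
    return Pathway(name=name, description=description, members=tuple(uniq))


def load_gmt(path: str | Path, source_label: str | None = None) -> PathwayCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    path = Path(path)
    pathways: list[Pathway] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, "
                f"got {len(fields)}"
            )
        name, description = fields[0].strip(), fields[1].strip()
        pw = make_pathway(name, description, fields[2:])
        if not pw.members:
            raise ParseError(f"{path}:{lineno}: pathway {name!r} has no members")
        pathways.append(pw)
    label = source_label if source_label is not None else path.stem
    return PathwayCollection(pathways=pathways, source_label=label)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in collection.pathways:
            fh.write("\t".join((p.name, p.description) + p.members) + "\n")


def member_indices(
    pathways: PathwayCollection, net: GeneNetwork
) -> dict[str, np.ndarray]:
    """In-network member indices per pathway (node-order aligned)."""
    out = {}
    for p in pathways.pathways:
        idx = [net.index[m] for m in p.members if m in net.index]
        out[p.name] = np.asarray(sorted(idx), dtype=np.intp)
    return out


def pathway_activity(
    gtilde: ActivityVector,
    pathways: PathwayCollection,
    net: GeneNetwork,
    min_members: int = 3,
    all_members: bool = False,
) -> pd.DataFrame:
    """Score each pathway as the mean member activity.

    Returns a frame indexed by pathway name (collection order) with
    columns ``score``, ``n_members``, ``n_in_network``, ``flagged``.
    Pathways with fewer than ``min_members`` in-network members are
    flagged and carry NaN scores (they are excluded from ranking, never
    imputed). With ``all_members=True`` the denominator is the full
    annotated size (absent members count as zero activity).
    """
    if gtilde.stage != "propagated":
        raise ValueError("pathway_activity requires a propagated vector")
    idx = member_indices(pathways, net)
    rows = []
    for p in pathways.pathways:
        members_in = idx[p.name]
        n_in = len(members_in)
        flagged = n_in < min_members
        if n_in == 0 or flagged:
            score = math.nan
        else:
            total = float(gtilde.scores[members_in].sum())
            denom = len(p.members) if all_members else n_in
            score = total / denom
        rows.append({
            "score": score,
            "n_members": len(p.members),
            "n_in_network": n_in,
            "flagged": flagged,
        })
    return pd.DataFrame(rows, index=pd.Index(pathways.names, name="pathway"))


@dataclass
class PathwayActivityMatrix:
    """Cancer x pathway activity scores with optional significance layers."""

    scores: pd.DataFrame                 # cancers x pathways
    coverage: pd.DataFrame               # same shape, in-network member counts
    collections: pd.Series | None = None  # pathway -> collection label
    p_values: pd.DataFrame | None = None
    q_values: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scores.shape != self.coverage.shape:
            raise ValueError("scores/coverage shape mismatch")
        for layer in (self.p_values, self.q_values):
            if layer is not None and layer.shape != self.scores.shape:
                raise ValueError("significance layer shape mismatch")

    @property
    def cancers(self) -> list[str]:
        return list(self.scores.index)

    @property
    def pathway_names(self) -> list[str]:
        return list(self.scores.columns)

    def collection_of(self, pathway: str) -> str:
        if self.collections is None:
            return "default"
        return str(self.collections[pathway])


def assemble_matrix(
    per_cancer_scores: Sequence[tuple[str, pd.DataFrame]],
    pathways: PathwayCollection | None = None,
) -> PathwayActivityMatrix:
    """Stack per-cancer score frames into a :class:`PathwayActivityMatrix`.

    Cancer rows keep input order; pathway columns follow the collection
    order (or the first cancer's order). Score frames may arrive with
    shuffled pathway order — values are placed by label.
    """
    if not per_cancer_scores:
        raise ValueError("no per-cancer scores given")
    first = per_cancer_scores[0][1]
    if pathways is not None:
        order = pathways.names
    else:
        order = list(first.index)
    ref = set(order)
    for label, frame in per_cancer_scores:
        if set(frame.index) != ref:
            raise ValueError(f"cancer {label!r} covers a different pathway set")
    labels = [label for label, _ in per_cancer_scores]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate cancer labels")
    scores = pd.DataFrame(
        {label: frame["score"].reindex(order) for label, frame in per_cancer_scores}
    ).T
    coverage = pd.DataFrame(
        {label: frame["n_in_network"].reindex(order) for label, frame in per_cancer_scores}
    ).T
    scores.index.name = coverage.index.name = "cancer"
    collections = None
    if pathways is not None:
        collections = pd.Series(
            {name: pathways.source_label for name in order}, name="collection"
        )
    return PathwayActivityMatrix(
        scores=scores, coverage=coverage, collections=collections
    )


def concat_matrices(matrices: Sequence[PathwayActivityMatrix]) -> PathwayActivityMatrix:
    """Concatenate matrices over pathway columns (same cancer rows)."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    cancers = matrices[0].scores.index
    for m in matrices[1:]:
        if not m.scores.index.equals(cancers):
            raise ValueError("cancer rows differ across matrices")
    scores = pd.concat([m.scores for m in matrices], axis=1)
    coverage = pd.concat([m.coverage for m in matrices], axis=1)
    if scores.columns.duplicated().any():
        raise ValueError("duplicate pathway names across collections")
    collections = pd.concat([
        m.collections if m.collections is not None
        else pd.Series({c: "default" for c in m.pathway_names})
        for m in matrices
    ])
    pv = None
    if all(m.p_values is not None for m in matrices):
        pv = pd.concat([m.p_values for m in matrices], axis=1)
    qv = None
    if all(m.q_values is not None for m in matrices):
        qv = pd.concat([m.q_values for m in matrices], axis=1)
    return PathwayActivityMatrix(
        scores=scores, coverage=coverage, collections=collections,
        p_values=pv, q_values=qv,
    )
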