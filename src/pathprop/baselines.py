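"""Overrepresentation baselines and cancer-gene fraction evaluation.

Pooled/aggregated analyses rank genes by -log10 q-value from the
copy-number significance tables, select the top k%, and test pathway
overlap with the hypergeometric upper tail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .graph import normalize_symbol

log = logging.getLogger(__name__)


@dataclass
class GeneSignificanceTable:
    """Per-gene -log10 q-values for amplification/deletion, one cancer type."""

    cancer_type: str
    frame: pd.DataFrame  # index: gene; columns: neg_log10_q_amp, neg_log10_q_del

    def __post_init__(self) -> None:
        for col in ("neg_log10_q_amp", "neg_log10_q_del"):
            if col not in self.frame.columns:
                self.frame[col] = np.nan
            vals = self.frame[col]
            if (vals.dropna() < 0).any():
                raise ValueError(f"{col} must be non-negative")
        if self.frame.index.duplicated().any():
            raise ValueError("duplicate genes in significance table")

    @classmethod
    def from_q_values(
        cls,
        cancer_type: str,
        q_amp: Mapping[str, float] | None = None,
        q_del: Mapping[str, float] | None = None,
    ) -> "GeneSignificanceTable":
        """Build from raw q-values; q=0 is clamped to the smallest positive q."""
        q_amp = dict(q_amp or {})
        q_del = dict(q_del or {})
        positive = [v for v in (*q_amp.values(), *q_del.values()) if v and v > 0]
        floor = min(positive) if positive else 1e-300
        clamped = False

        def nlq(q):
            nonlocal clamped
            if q is None or (isinstance(q, float) and math.isnan(q)):
                return np.nan
            if q <= 0:
                clamped = True
                q = floor
            return -math.log10(q)

        genes = sorted({normalize_symbol(g) for g in (*q_amp, *q_del)})
        frame = pd.DataFrame(
            {
                "neg_log10_q_amp": [nlq(q_amp.get(g)) for g in genes],
                "neg_log10_q_del": [nlq(q_del.get(g)) for g in genes],
            },
            index=pd.Index(genes, name="gene"),
        )
        if clamped:
            log.warning("%s: q=0 clamped to %.3g", cancer_type, floor)
        return cls(cancer_type=cancer_type, frame=frame)

    @classmethod
    def from_seed_table(cls, table) -> "GeneSignificanceTable":
        q_amp, q_del = {}, {}
        for rec in table.records:
            if rec.q_value is None:
                continue
            (q_amp if rec.alteration == "amp" else q_del)[rec.gene] = rec.q_value
        return cls.from_q_values(table.cancer_type, q_amp, q_del)

    def gene_scores(self) -> pd.Series:
        """Per-gene significance: max of amp/del, missing treated as 0."""
        return self.frame.fillna(0.0).max(axis=1)

    @property
    def genes(self) -> set[str]:
        return set(self.frame.index)


def _top_fraction(scores: pd.Series, top_fraction: float) -> set[str]:
    if scores.empty:
        raise ValueError("empty gene significance table")
    k = int(math.ceil(top_fraction * len(scores)))
    ranked = sorted(scores.index, key=lambda g: (-scores[g], g))
    return set(ranked[:k])


def gene_ranking_pooled(
    table: GeneSignificanceTable, top_fraction: float
) -> set[str]:
    """Top-k% genes of a pooled (all patients combined) significance table."""
    return _top_fraction(table.gene_scores(), top_fraction)


def gene_ranking_aggregated(
    tables: Sequence[GeneSignificanceTable], top_fraction: float
) -> set[str]:
    """Top-k% genes by -log10 q summed over cancer types (missing = 0)."""
    if not tables:
        raise ValueError("no significance tables given")
    total: pd.Series | None = None
    for t in tables:
        s = t.gene_scores()
        total = s if total is None else total.add(s, fill_value=0.0)
    return _top_fraction(total, top_fraction)


def hypergeometric_enrichment(
    selected: Iterable[str], pathway_members: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p for the selected/pathway overlap."""
    universe = set(universe)
    selected = set(selected)
    members = set(pathway_members)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    if not members <= universe:
        raise ValueError("pathway members must be a subset of the universe")
    overlap = len(selected & members)
    # P(X >= overlap), X ~ Hypergeom(M=|universe|, n=|members|, N=|selected|)
    return float(hypergeom.sf(overlap - 1, len(universe), len(members), len(selected)))


def enrichment_table(
    selected: set[str],
    pathways,
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric p per pathway (members clipped to the universe)."""
    rows = []
    for p in pathways.pathways:
        members = set(p.members) & universe
        pv = hypergeometric_enrichment(selected, members, universe)
        rows.append({
            "pathway": p.name,
            "overlap": len(selected & members),
            "pathway_size": len(members),
            "p_value": pv,
        })
    return pd.DataFrame(rows).set_index("pathway")


def load_census(path: str | Path) -> set[str]:
    """Cancer-gene reference list: one symbol per line."""
    return {
        normalize_symbol(ln)
        for ln in Path(path).read_text().splitlines()
        if ln.strip()
    }


def cancer_gene_fraction(
    module_genes: Iterable[str],
    census: Iterable[str],
    gene_pool: Iterable[str] | None = None,
    n_controls: int = 0,
    rng_seed: int = 0,
) -> dict:
    """Fraction of module genes found in the cancer-gene reference.

    With ``n_controls > 0`` also samples size-matched random gene sets
    from ``gene_pool`` for an empirical comparison.
    """
    module = set(module_genes)
    if not module:
        raise ValueError("empty functional module")
    census = set(census)
    fraction = len(module & census) / len(module)
    out: dict = {"fraction": fraction, "module_size": len(module)}
    if n_controls > 0:
        if gene_pool is None:
            raise ValueError("gene_pool required for control resampling")
        pool = sorted(set(gene_pool))
        if len(pool) < len(module):
            raise ValueError("gene pool smaller than module")
        rng = np.random.default_rng(rng_seed)
        controls = np.empty(n_controls)
        for b in range(n_controls):
            draw = rng.choice(len(pool), size=len(module), replace=False)
            picked = {pool[i] for i in draw}
            controls[b] = len(picked & census) / len(module)
        out["control_fractions"] = controls
        out["control_mean"] = float(controls.mean())
        out["control_sd"] = float(controls.std(ddof=1)) if n_controls > 1 else 0.0
    return out
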