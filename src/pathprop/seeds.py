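"""Copy-number seed genes: table parsing and initial activity vectors.

Seed genes (those inside recurrently amplified/deleted regions) carry an
initial activity score equal to their average log2 copy-number ratio; all
other network genes start at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, SchemaError
from .graph import GeneNetwork, normalize_symbol

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("gene", "alteration", "avg_log2_ratio")
OPTIONAL_COLUMNS = ("q_value", "frequency", "arm_level")
VALID_ALTERATIONS = ("amp", "del")

_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no"}


class SeedRecord(NamedTuple):
    gene: str
    alteration: str
    avg_log2_ratio: float
    q_value: float | None
    frequency: float | None
    arm_level: bool | None


@dataclass
class SeedGeneTable:
    """Gene-level alteration records for one cancer type."""

    cancer_type: str
    frame: pd.DataFrame  # columns: gene, alteration, avg_log2_ratio, q_value, frequency, arm_level

    def __post_init__(self) -> None:
        for col in OPTIONAL_COLUMNS:
            if col not in self.frame.columns:
                self.frame[col] = None
        dup = self.frame.duplicated(subset=["gene", "alteration"])
        if dup.any():
            bad = sorted(self.frame.loc[dup, "gene"].unique())
            raise SchemaError(
                f"duplicate (gene, alteration) records for: {', '.join(bad)}"
            )
        bad_alt = ~self.frame["alteration"].isin(VALID_ALTERATIONS)
        if bad_alt.any():
            labels = sorted(self.frame.loc[bad_alt, "alteration"].unique())
            raise SchemaError(f"unknown alteration labels: {labels}")
        q = pd.to_numeric(self.frame["q_value"], errors="coerce")
        out_of_range = q.notna() & ((q < 0) | (q > 1))
        if out_of_range.any():
            raise SchemaError("q_value outside [0, 1]")

    @property
    def records(self) -> list[SeedRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            out.append(SeedRecord(
                gene=row.gene,
                alteration=row.alteration,
                avg_log2_ratio=float(row.avg_log2_ratio),
                q_value=None if pd.isna(row.q_value) else float(row.q_value),
                frequency=None if pd.isna(row.frequency) else float(row.frequency),
                arm_level=None if pd.isna(row.arm_level) else bool(row.arm_level),
            ))
        return out

    @property
    def genes(self) -> set[str]:
        return set(self.frame["gene"])

    def has_q_values(self) -> bool:
        return self.frame["q_value"].notna().any()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class PatientLogRatioMatrix:
    """Per-patient log2 ratios: genes x patients."""

    genes: list[str]
    patients: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.genes), len(self.patients)):
            raise ValueError("matrix shape inconsistent with gene/patient lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in log-ratio matrix")


@dataclass
class ActivityVector:
    """Per-gene activity scores aligned to a network node order."""

    scores: np.ndarray
    stage: str = "initial"  # {"initial", "propagated"}

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.stage not in ("initial", "propagated"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite activity scores")


def _parse_bool(value, lineno: int, path: Path):
    if pd.isna(value):
        return None
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ParseError(f"{path}:{lineno}: cannot parse arm_level value {value!r}")


def load_seed_table(path: str | Path, cancer_type: str | None = None) -> SeedGeneTable:
    """Load a seed-gene TSV (``gene  alteration  avg_log2_ratio [q_value frequency arm_level]``).

    The cancer label defaults to the filename stem.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    df["gene"] = df["gene"].map(normalize_symbol)
    df["alteration"] = df["alteration"].str.strip().str.lower()
    for col in ("avg_log2_ratio", "q_value", "frequency"):
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            lineno = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(
                f"{path}:{lineno}: non-numeric {col} value {df[col][bad.idxmax()]!r}"
            )
        df[col] = converted
    if df["avg_log2_ratio"].isna().any():
        lineno = int(df["avg_log2_ratio"].isna().idxmax()) + 2
        raise ParseError(f"{path}:{lineno}: missing avg_log2_ratio")
    if "arm_level" in df.columns:
        df["arm_level"] = [
            _parse_bool(v, i + 2, path) for i, v in enumerate(df["arm_level"])
        ]
    label = cancer_type if cancer_type is not None else path.stem
    return SeedGeneTable(cancer_type=label, frame=df.reset_index(drop=True))


def load_patient_matrix(path: str | Path) -> PatientLogRatioMatrix:
    """Load a gene x patient log2-ratio TSV (first column = gene)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    genes = [normalize_symbol(g) for g in df.index]
    return PatientLogRatioMatrix(
        genes=genes, patients=list(df.columns), values=df.to_numpy(dtype=np.float64)
    )


def averages_from_matrix(
    mat: PatientLogRatioMatrix,
    amp_genes: Iterable[str],
    del_genes: Iterable[str],
    cancer_type: str = "unnamed",
) -> SeedGeneTable:
    """Average each seed gene's log2 ratio over patient columns."""
    amp = {normalize_symbol(g) for g in amp_genes}
    dele = {normalize_symbol(g) for g in del_genes}
    available = set(mat.genes)
    missing = sorted((amp | dele) - available)
    if missing:
        raise SchemaError(f"seed genes absent from matrix: {', '.join(missing)}")
    idx = {g: i for i, g in enumerate(mat.genes)}
    rows = []
    for alteration, genes in (("amp", amp), ("del", dele)):
        for g in sorted(genes):
            rows.append({
                "gene": g,
                "alteration": alteration,
                "avg_log2_ratio": float(mat.values[idx[g]].mean()),
            })
    return SeedGeneTable(cancer_type=cancer_type, frame=pd.DataFrame(rows))


def filter_arm_level(table: SeedGeneTable, exclude: bool) -> SeedGeneTable:
    """Optionally drop records flagged as whole-arm events."""
    if not exclude:
        return table
    if table.frame["arm_level"].isna().all():
        raise ConfigurationError(
            "arm-level exclusion requested but arm_level column is absent"
        )
    keep = table.frame["arm_level"] != True  # noqa: E712 (None kept)
    out = table.frame[keep].reset_index(drop=True)
    if out.empty:
        log.warning(
            "%s: all records were arm-level; seed table is now empty",
            table.cancer_type,
        )
    return SeedGeneTable(cancer_type=table.cancer_type, frame=out)


def resolve_gene_scores(table: SeedGeneTable) -> pd.Series:
    """Per-gene signed average log2 ratio after amp/del conflict resolution.

    A gene recorded under both alterations takes the record with larger
    magnitude; ties go to the amplification record.
    """
    frame = table.frame.copy()
    frame["_mag"] = frame["avg_log2_ratio"].abs()
    frame["_amp_first"] = (frame["alteration"] == "amp").astype(int)
    frame = frame.sort_values(
        ["gene", "_mag", "_amp_first"], ascending=[True, False, False]
    )
    best = frame.drop_duplicates(subset="gene", keep="first")
    return pd.Series(
        best["avg_log2_ratio"].to_numpy(dtype=float), index=best["gene"].to_numpy()
    )


def initial_scores(
    table: SeedGeneTable, net: GeneNetwork, mode: str = "magnitude"
) -> ActivityVector:
    """Build the initial activity vector g aligned to the network node order.

    ``magnitude`` (default) uses |avg log2 ratio| so amplifications and
    deletions both count as disruption; ``signed`` keeps raw values for
    sensitivity analysis. Seed genes absent from the network are dropped
    with a logged count.
    """
    if mode not in ("magnitude", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    per_gene = resolve_gene_scores(table)
    g = np.zeros(net.n_nodes, dtype=np.float64)
    dropped = 0
    for gene, value in per_gene.items():
        i = net.index.get(gene)
        if i is None:
            dropped += 1
            continue
        g[i] = abs(value) if mode == "magnitude" else value
    if dropped:
        log.info(
            "%s: %d of %d seed genes absent from network, dropped",
            table.cancer_type, dropped, len(per_gene),
        )
    return ActivityVector(scores=g, stage="initial")


def annotation_coverage(table: SeedGeneTable, pathways) -> dict[str, float]:
    """Fraction of seed genes annotated in at least one pathway."""
    seed_genes = table.genes
    if not seed_genes:
        raise ValueError("empty seed table")
    annotated_universe: set[str] = set()
    for pw in pathways.pathways:
        annotated_universe.update(pw.members)
    n_annotated = len(seed_genes & annotated_universe)
    frac = n_annotated / len(seed_genes)
    return {
        "n_seed_genes": len(seed_genes),
        "n_annotated": n_annotated,
        "annotated_fraction": frac,
        "unannotated_fraction": 1.0 - frac,
    }


def write_activity_tsv(
    net: GeneNetwork,
    initial: ActivityVector,
    propagated: ActivityVector,
    path: str | Path,
) -> None:
    """Write gene, initial_score, propagated_score TSV."""
    with open(path, "w") as fh:
        fh.write("gene\tinitial_score\tpropagated_score\n")
        for i, gene in enumerate(net.nodes):
            fh.write(f"{gene}\t{initial.scores[i]:.10g}\t{propagated.scores[i]:.10g}\n")
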