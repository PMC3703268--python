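"""Synthetic networks, pathway collections, seed tables and decoys.

Real inputs (tumor copy-number portals, interaction databases, curated
gene sets) are external resources; this module generates structurally
similar instances with planted ground truth so the whole pipeline is
testable offline. Alteration magnitudes are lognormal around a target
mean; planted disruption comes in two flavors: ``direct`` (altered genes
inside the target pathway) and ``neighbor_only`` (altered genes strictly
among direct interactors of members, never members themselves).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .graph import GeneNetwork
from .scoring import PathwayCollection, make_pathway, write_gmt
from .seeds import SeedGeneTable

NETWORK_MODELS = ("erdos_renyi", "preferential_attachment", "community")
SCENARIOS = ("direct", "neighbor_only", "null")


@dataclass
class ScenarioSpec:
    n_genes: int = 2000
    network_model: str = "erdos_renyi"
    avg_degree: float = 8.0
    n_pathways: int = 200
    pathway_size_range: tuple[int, int] = (10, 30)
    n_cancers: int = 16
    scenario: str = "null"
    effect_size: float = 2.0          # mean |log2 ratio| of planted altered genes
    background_effect_size: float = 0.3
    altered_fraction: float = 0.05    # background altered genes per cancer
    n_planted: int = 1
    planted_in_cancers: int | None = None  # default: all cancers
    member_altered_fraction: float = 0.5   # direct scenario only
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.network_model not in NETWORK_MODELS:
            raise ValueError(f"unknown network model {self.network_model!r}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid pathway_size_range")
        if hi > self.n_genes:
            raise ValueError("pathway size exceeds gene count")
        if not 0.0 < self.altered_fraction < 1.0:
            raise ValueError("altered_fraction must be in (0, 1)")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if min(self.n_genes, self.n_pathways, self.n_cancers) < 1:
            raise ValueError("sizes must be positive")


@dataclass
class SyntheticInstance:
    network: GeneNetwork
    pathways: PathwayCollection
    seed_tables: list[SeedGeneTable]
    truth: dict[str, list[str]]  # planted pathway -> cancers planted in
    spec: ScenarioSpec


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _make_graph(spec: ScenarioSpec, rng: np.random.Generator) -> nx.Graph:
    seed = int(rng.integers(2**31 - 1))
    n = spec.n_genes
    if spec.network_model == "erdos_renyi":
        p = min(spec.avg_degree / max(n - 1, 1), 1.0)
        return nx.fast_gnp_random_graph(n, p, seed=seed)
    if spec.network_model == "preferential_attachment":
        m = max(1, round(spec.avg_degree / 2))
        return nx.barabasi_albert_graph(n, m, seed=seed)
    # community: planted partition, ~80% of each node's degree inside its block
    n_blocks = max(2, n // 100)
    block = n // n_blocks
    p_in = min(0.8 * spec.avg_degree / max(block - 1, 1), 1.0)
    p_out = min(0.2 * spec.avg_degree / max(n - block, 1), 1.0)
    graph = nx.planted_partition_graph(n_blocks, block, p_in, p_out, seed=seed)
    # pad to exactly n nodes when n is not divisible by the block count
    for extra in range(graph.number_of_nodes(), n):
        graph.add_node(extra)
        targets = rng.choice(extra, size=min(3, extra), replace=False)
        for t in targets:
            graph.add_edge(extra, int(t))
    return graph


def _connected_gene_set(
    graph: nx.Graph, size: int, rng: np.random.Generator
) -> list[int]:
    """BFS ball around a random start node, truncated to ``size`` nodes."""
    start = int(rng.integers(graph.number_of_nodes()))
    seen = [start]
    seen_set = {start}
    frontier = [start]
    while len(seen) < size and frontier:
        nxt = []
        for node in frontier:
            for nb in sorted(graph.neighbors(node)):
                if nb not in seen_set:
                    seen_set.add(nb)
                    seen.append(nb)
                    nxt.append(nb)
                    if len(seen) >= size:
                        return seen
        frontier = nxt
    while len(seen) < size:  # disconnected pocket: pad with random nodes
        cand = int(rng.integers(graph.number_of_nodes()))
        if cand not in seen_set:
            seen_set.add(cand)
            seen.append(cand)
    return seen


def _magnitudes(
    n: int, mean: float, rng: np.random.Generator, sigma: float = 0.25
) -> np.ndarray:
    """Lognormal magnitudes with the requested mean."""
    mu = math.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, size=n)


def _seed_rows(
    genes: Iterable[str],
    magnitudes: np.ndarray,
    rng: np.random.Generator,
    arm_fraction: float = 0.1,
) -> list[dict]:
    rows = []
    for gene, mag in zip(genes, magnitudes):
        amp = bool(rng.random() < 0.5)
        rows.append({
            "gene": gene,
            "alteration": "amp" if amp else "del",
            "avg_log2_ratio": float(mag if amp else -mag),
            "q_value": float(10.0 ** (-rng.uniform(2.0, 8.0))),
            "frequency": float(rng.uniform(0.1, 0.9)),
            "arm_level": bool(rng.random() < arm_fraction),
        })
    return rows


def generate_instance(spec: ScenarioSpec) -> SyntheticInstance:
    """Deterministically build a network, pathways, seed tables and truth labels."""
    rng = np.random.default_rng(spec.rng_seed)
    graph = _make_graph(spec, rng)
    names = _gene_names(spec.n_genes)
    edges = [(names[a], names[b]) for a, b in graph.edges()]
    net = GeneNetwork.from_edges(edges, extra_nodes=names)

    # planted pathways are connected neighborhoods; decoy-free background
    # pathways are uniform random gene sets
    lo, hi = spec.pathway_size_range
    pathways = []
    planted_members: dict[str, list[int]] = {}
    n_planted = spec.n_planted if spec.scenario != "null" else 0
    for j in range(spec.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if j < n_planted:
            node_ids = _connected_gene_set(graph, size, rng)
            name = f"PLANTED_{j:03d}"
            planted_members[name] = node_ids
        else:
            node_ids = list(rng.choice(spec.n_genes, size=size, replace=False))
            name = f"PATHWAY_{j:03d}"
        pathways.append(
            make_pathway(name, "synthetic", [names[i] for i in node_ids])
        )
    collection = PathwayCollection(pathways=pathways, source_label="synthetic")

    planted_cancer_count = (
        spec.planted_in_cancers
        if spec.planted_in_cancers is not None
        else spec.n_cancers
    )
    planted_cancer_count = min(planted_cancer_count, spec.n_cancers)
    cancer_labels = [f"CANCER_{k:02d}" for k in range(spec.n_cancers)]
    planted_cancers = cancer_labels[:planted_cancer_count]

    protected: set[int] = set()
    if spec.scenario == "neighbor_only":
        # members must never be altered anywhere the signal is planted
        for ids in planted_members.values():
            protected.update(ids)

    n_background = max(1, round(spec.altered_fraction * spec.n_genes))
    seed_tables = []
    for label in cancer_labels:
        is_planted_cancer = label in planted_cancers and spec.scenario != "null"
        altered: dict[int, float] = {}
        if is_planted_cancer:
            for ids in planted_members.values():
                if spec.scenario == "direct":
                    k = max(1, math.ceil(spec.member_altered_fraction * len(ids)))
                    chosen = list(rng.choice(ids, size=k, replace=False))
                else:  # neighbor_only
                    member_set = set(ids)
                    neighbors = sorted({
                        nb for i in ids for nb in graph.neighbors(i)
                        if nb not in member_set
                    })
                    chosen = neighbors
                mags = _magnitudes(len(chosen), spec.effect_size, rng)
                for node, mag in zip(chosen, mags):
                    altered[int(node)] = float(mag)
        pool = [
            i for i in range(spec.n_genes)
            if i not in altered and (not is_planted_cancer or i not in protected)
        ]
        chosen_bg = rng.choice(len(pool), size=min(n_background, len(pool)), replace=False)
        bg_nodes = [pool[i] for i in chosen_bg]
        bg_mags = _magnitudes(len(bg_nodes), spec.background_effect_size, rng)
        for node, mag in zip(bg_nodes, bg_mags):
            altered[int(node)] = float(mag)
        ordered = sorted(altered)
        rows = _seed_rows(
            [names[i] for i in ordered],
            np.array([altered[i] for i in ordered]),
            rng,
        )
        seed_tables.append(
            SeedGeneTable(cancer_type=label, frame=pd.DataFrame(rows))
        )

    truth = (
        {name: list(planted_cancers) for name in planted_members}
        if spec.scenario != "null"
        else {}
    )
    return SyntheticInstance(
        network=net, pathways=collection, seed_tables=seed_tables,
        truth=truth, spec=spec,
    )


def generate_decoys(
    pathways: PathwayCollection,
    n_decoys: int,
    gene_pool: Iterable[str],
    rng_seed: int = 0,
) -> PathwayCollection:
    """Uniform random gene sets size-matched to sampled real pathways."""
    if n_decoys < 1:
        raise ValueError("n_decoys must be >= 1")
    pool = sorted(set(gene_pool))
    rng = np.random.default_rng(rng_seed)
    sizes = [
        len(pathways.pathways[int(i)].members)
        for i in rng.integers(len(pathways.pathways), size=n_decoys)
    ]
    if max(sizes) > len(pool):
        raise ValueError("gene pool smaller than the largest requested decoy")
    decoys = []
    for j, size in enumerate(sizes):
        picked = rng.choice(len(pool), size=size, replace=False)
        decoys.append(
            make_pathway(f"DECOY_{j:04d}", "decoy", [pool[i] for i in picked])
        )
    return PathwayCollection(
        pathways=decoys, source_label=f"{pathways.source_label}_decoys"
    )


def write_instance(instance: SyntheticInstance, outdir: str | Path) -> dict:
    """Write an instance in the formats the pipeline reads; returns the manifest."""
    from .graph import write_edge_list

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_edge_list(instance.network, outdir / "network.tsv")
    write_gmt(instance.pathways, outdir / "pathways.gmt")
    seeds_dir = outdir / "seeds"
    seeds_dir.mkdir(exist_ok=True)
    seed_paths = {}
    for table in instance.seed_tables:
        path = seeds_dir / f"{table.cancer_type}.tsv"
        frame = table.frame.copy()
        frame["arm_level"] = frame["arm_level"].map(
            lambda v: "" if pd.isna(v) else str(bool(v)).lower()
        )
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        seed_paths[table.cancer_type] = str(path.relative_to(outdir))
    manifest = {
        "network": "network.tsv",
        "collections": [{"label": "synthetic", "path": "pathways.gmt"}],
        "seed_tables": seed_paths,
        "truth": instance.truth,
        "scenario": instance.spec.scenario,
        "rng_seed": instance.spec.rng_seed,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
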