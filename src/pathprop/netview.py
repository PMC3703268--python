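"""Per-pathway disruption neighborhoods for network visualization.

A neighborhood holds all in-network pathway members plus those direct
interactors whose copy-number q-value ranks among the most significant
(top-N, ties at the boundary included), with alteration status,
frequency and magnitude attached for rendering (size ~ frequency;
red = amplified, green = deleted, gray = unchanged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .graph import GeneNetwork
from .scoring import PathwayCollection
from .seeds import SeedGeneTable


@dataclass
class PathwayNeighborhood:
    pathway: str
    nodes: pd.DataFrame  # index: gene; columns: layer, status, frequency, avg_log2_ratio
    edges: list[tuple[str, str]]  # lexicographically sorted pairs

    def __post_init__(self) -> None:
        members = set(self.nodes.index[self.nodes["layer"] == "member"])
        for gene, layer in self.nodes["layer"].items():
            if layer not in ("member", "interactor"):
                raise ValueError(f"bad layer {layer!r} for {gene}")
        adjacency: dict[str, set[str]] = {}
        for a, b in self.edges:
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)
        for gene in self.nodes.index[self.nodes["layer"] == "interactor"]:
            if not adjacency.get(gene, set()) & members:
                raise ValueError(f"interactor {gene} touches no member")

    @property
    def members(self) -> list[str]:
        return sorted(self.nodes.index[self.nodes["layer"] == "member"])

    @property
    def interactors(self) -> list[str]:
        return sorted(self.nodes.index[self.nodes["layer"] == "interactor"])


def _gene_attributes(seed_table: SeedGeneTable) -> pd.DataFrame:
    """Per-gene status/frequency/magnitude/q (conflicts: larger magnitude, tie amp)."""
    frame = seed_table.frame.copy()
    frame["_mag"] = frame["avg_log2_ratio"].abs()
    frame["_amp_first"] = (frame["alteration"] == "amp").astype(int)
    best = frame.sort_values(
        ["gene", "_mag", "_amp_first"], ascending=[True, False, False]
    ).drop_duplicates(subset="gene", keep="first")
    # q-value for ranking interactors: the more significant of amp/del
    min_q = frame.groupby("gene")["q_value"].min()
    out = best.set_index("gene")[["alteration", "avg_log2_ratio", "frequency"]]
    out["q_value"] = min_q
    return out


def build_neighborhood(
    pathway: str,
    pathways: PathwayCollection,
    net: GeneNetwork,
    seed_table: SeedGeneTable,
    top_n_qvalue: int = 500,
    include_interactor_edges: bool = True,
) -> PathwayNeighborhood:
    """Assemble the neighborhood of one pathway for one cancer type.

    Members are always included; a non-member direct interactor is kept
    only if its q-value rank (ascending) falls within ``top_n_qvalue``,
    with boundary ties included.
    """
    pw = pathways[pathway]  # KeyError for unknown pathway names
    if not seed_table.has_q_values():
        raise ValueError("seed table carries no q_value column; cannot rank interactors")
    attrs = _gene_attributes(seed_table)
    ranked_q = attrs["q_value"].dropna().sort_values(kind="stable")
    if len(ranked_q) > top_n_qvalue:
        boundary = float(ranked_q.iloc[top_n_qvalue - 1])
        eligible = set(ranked_q.index[ranked_q <= boundary])
    else:
        eligible = set(ranked_q.index)

    members = sorted(m for m in pw.members if m in net.index)
    member_set = set(members)
    interactors = sorted({
        nb
        for m in members
        for nb in net.neighbors(m)
        if nb not in member_set and nb in eligible
    })
    included = members + interactors
    included_set = set(included)

    rows = []
    for gene in included:
        layer = "member" if gene in member_set else "interactor"
        if gene in attrs.index:
            status = attrs.loc[gene, "alteration"]
            frequency = attrs.loc[gene, "frequency"]
            magnitude = attrs.loc[gene, "avg_log2_ratio"]
        else:
            status, frequency, magnitude = "unchanged", math.nan, math.nan
        rows.append({
            "gene": gene, "layer": layer, "status": status,
            "frequency": float(frequency) if pd.notna(frequency) else math.nan,
            "avg_log2_ratio": float(magnitude) if pd.notna(magnitude) else math.nan,
        })
    node_frame = pd.DataFrame(rows).set_index("gene")

    edges = []
    for a in included:
        for b in net.neighbors(a):
            if b <= a or b not in included_set:
                continue
            both_interactors = a not in member_set and b not in member_set
            if both_interactors and not include_interactor_edges:
                continue
            edges.append((a, b))
    edges.sort()
    # interactors orphaned by edge filtering cannot occur: each was found
    # through a member adjacency, and member-interactor edges are kept
    return PathwayNeighborhood(pathway=pathway, nodes=node_frame, edges=edges)


def export_neighborhood(
    nb: PathwayNeighborhood, out_prefix: str | Path, fmt: str = "sif"
) -> list[Path]:
    """Write the neighborhood as SIF + node-attribute TSV, or GraphML."""
    out_prefix = Path(out_prefix)
    if fmt == "sif":
        sif = out_prefix.with_suffix(".sif")
        with open(sif, "w") as fh:
            for a, b in nb.edges:
                fh.write(f"{a}\tpp\t{b}\n")
        attr = out_prefix.with_suffix(".nodes.tsv")
        with open(attr, "w") as fh:
            fh.write("gene\tlayer\tstatus\tfrequency\tavg_log2_ratio\n")
            for gene, row in nb.nodes.iterrows():
                freq = "" if math.isnan(row["frequency"]) else f"{row['frequency']:.6g}"
                mag = "" if math.isnan(row["avg_log2_ratio"]) else f"{row['avg_log2_ratio']:.6g}"
                fh.write(f"{gene}\t{row['layer']}\t{row['status']}\t{freq}\t{mag}\n")
        return [sif, attr]
    if fmt == "graphml":
        graph = nx.Graph()
        for gene, row in nb.nodes.iterrows():
            attrs = {"layer": row["layer"], "status": row["status"]}
            if not math.isnan(row["frequency"]):
                attrs["frequency"] = float(row["frequency"])
            if not math.isnan(row["avg_log2_ratio"]):
                attrs["avg_log2_ratio"] = float(row["avg_log2_ratio"])
            graph.add_node(gene, **attrs)
        graph.add_edges_from(nb.edges)
        path = out_prefix.with_suffix(".graphml")
        nx.write_graphml(graph, path)
        return [path]
    raise ValueError(f"unsupported export format {fmt!r}")
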