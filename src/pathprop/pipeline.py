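"""End-to-end orchestration: propagate, score, test, select, report.

A run is fully described by a :class:`RunConfig`; identical configs and
seeds yield byte-identical score matrices and manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .graph import load_edge_list, normalized_adjacency, write_node_manifest
from .propagation import PropagationConfig, propagate
from .scoring import (
    PathwayActivityMatrix,
    assemble_matrix,
    load_gmt,
    pathway_activity,
)
from .seeds import initial_scores, load_seed_table, write_activity_tsv
from .significance import (
    PermutationConfig,
    SelectionCriteria,
    attach_significance,
    empirical_pvalues,
    permutation_null,
    select_common,
    select_per_cancer,
    select_specific,
)

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    network: str
    collections: list[dict]          # [{"label": ..., "path": ...}]
    seed_tables: dict[str, str]      # cancer label -> path
    output: str = "pathprop_out"
    node_file: str | None = None
    census: str | None = None
    seed: int = 0
    exclude_arm_level: bool = False
    score_mode: str = "magnitude"
    min_members: int = 3
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    max_specific_cancers: int = 2
    run_patterns: bool = True
    run_baselines: bool = False
    netview_pathways: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        base_dir = Path(path).parent
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})

        def resolve(p):
            p = Path(p)
            return str(p if p.is_absolute() else base_dir / p)

        prop = PropagationConfig(**raw.pop("propagation", {}))
        perm = PermutationConfig(**raw.pop("permutation", {}))
        sel = SelectionCriteria(**raw.pop("selection", {}))
        raw["network"] = resolve(raw["network"])
        raw["collections"] = [
            {"label": c["label"], "path": resolve(c["path"])}
            for c in raw["collections"]
        ]
        raw["seed_tables"] = {
            label: resolve(p) for label, p in raw["seed_tables"].items()
        }
        for key in ("node_file", "census"):
            if raw.get(key):
                raw[key] = resolve(raw[key])
        raw.pop("truth", None)
        raw.pop("scenario", None)
        raw.pop("rng_seed", None)
        return cls(propagation=prop, permutation=perm, selection=sel, **raw)

    def validate(self) -> None:
        for p in [self.network, *(c["path"] for c in self.collections),
                  *self.seed_tables.values()]:
            if not Path(p).exists():
                raise ConfigurationError(f"input path does not exist: {p}")
        if not self.seed_tables:
            raise ConfigurationError("no seed tables configured")
        if not self.collections:
            raise ConfigurationError("no pathway collections configured")


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory."""
    cfg.validate()
    outdir = Path(cfg.output)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("loading network from %s", cfg.network)
    net = load_edge_list(cfg.network, node_file=cfg.node_file)
    gbar = normalized_adjacency(net)
    write_node_manifest(net, outdir / "nodes.tsv")

    collections = [
        load_gmt(c["path"], source_label=c["label"]) for c in cfg.collections
    ]

    from .seeds import filter_arm_level

    propagated = {}
    initial = {}
    seed_tables = {}
    for label, path in cfg.seed_tables.items():
        table = load_seed_table(path, cancer_type=label)
        table = filter_arm_level(table, cfg.exclude_arm_level)
        seed_tables[label] = table
        g0 = initial_scores(table, net, mode=cfg.score_mode)
        gt = propagate(gbar, g0, cfg.propagation)
        initial[label], propagated[label] = g0, gt
        write_activity_tsv(net, g0, gt, outdir / f"activity_{label}.tsv")

    cfg_dict = _to_jsonable(cfg)
    cfg_dict.pop("output", None)  # keep manifests byte-identical across out dirs
    manifest: dict = {
        "package_version": __version__,
        "config": cfg_dict,
        "network": {"n_nodes": net.n_nodes, "n_edges": net.n_edges},
        "cancers": sorted(cfg.seed_tables),
        "collections": {},
        "selections": {},
    }

    all_common = {}
    for collection in collections:
        label = collection.source_label
        per_cancer = []
        for cancer in cfg.seed_tables:
            frame = pathway_activity(
                propagated[cancer], collection, net, min_members=cfg.min_members
            )
            per_cancer.append((cancer, frame))
        matrix = assemble_matrix(per_cancer, pathways=collection)

        pvals = {}
        for cancer in cfg.seed_tables:
            nulls, names = permutation_null(
                net, gbar, initial[cancer], collection,
                cfg.permutation, cfg.propagation,
            )
            observed = matrix.scores.loc[cancer]
            pvals[cancer] = empirical_pvalues(observed, nulls, names=names)
        p_frame = pd.DataFrame(pvals).T.reindex(
            index=matrix.scores.index, columns=matrix.scores.columns
        )
        matrix = attach_significance(matrix, p_frame)

        prefix = outdir / f"{label}"
        matrix.scores.to_csv(f"{prefix}_scores.tsv", sep="\t", float_format=_FLOAT_FMT)
        matrix.coverage.to_csv(f"{prefix}_coverage.tsv", sep="\t", float_format=_FLOAT_FMT)
        matrix.p_values.to_csv(f"{prefix}_pvalues.tsv", sep="\t", float_format=_FLOAT_FMT)
        matrix.q_values.to_csv(f"{prefix}_qvalues.tsv", sep="\t", float_format=_FLOAT_FMT)

        cutoffs = cfg.permutation.fdr_cutoffs
        per_cancer_sel = select_per_cancer(matrix, cfg.selection, cutoffs)
        common = select_common(matrix, cfg.selection, cutoffs)
        specific = select_specific(
            matrix, cfg.selection, cutoffs, max_cancer_types=cfg.max_specific_cancers
        )
        common.to_csv(f"{prefix}_common.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)
        with open(f"{prefix}_per_cancer.tsv", "w") as fh:
            fh.write("cancer\tpathway\n")
            for cancer in sorted(per_cancer_sel):
                for name in per_cancer_sel[cancer]:
                    fh.write(f"{cancer}\t{name}\n")
        with open(f"{prefix}_specific.tsv", "w") as fh:
            fh.write("cancer\tpathway\n")
            for cancer in sorted(specific):
                for name in specific[cancer]:
                    fh.write(f"{cancer}\t{name}\n")

        all_common[label] = common
        manifest["collections"][label] = {
            "n_pathways": len(collection),
        }
        manifest["selections"][label] = {
            "per_cancer_counts": {c: len(v) for c, v in per_cancer_sel.items()},
            "n_common": int(len(common)),
            "n_specific": sum(len(v) for v in specific.values()),
        }

        if cfg.run_patterns and matrix.scores.shape[0] >= 2:
            _write_patterns(matrix, prefix)

        for pathway_name in cfg.netview_pathways:
            if pathway_name not in collection.names:
                continue
            from .netview import build_neighborhood, export_neighborhood
            for cancer, table in seed_tables.items():
                if not table.has_q_values():
                    continue
                nb = build_neighborhood(pathway_name, collection, net, table)
                export_neighborhood(
                    nb, outdir / f"netview_{label}_{cancer}_{pathway_name}", "sif"
                )

    if cfg.run_baselines and cfg.census:
        _write_baselines(cfg, seed_tables, collections, all_common, outdir)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def _write_patterns(matrix: PathwayActivityMatrix, prefix) -> None:
    from .patterns import codisruption_correlation, hierarchical_cluster, zscore_by_cancer

    z = zscore_by_cancer(matrix)
    complete = z.scores.dropna(axis=1)
    if complete.shape[1] >= 2 and complete.shape[0] >= 2:
        result = hierarchical_cluster(complete, axis="both")
        ordered = complete.loc[result.row_order, result.column_order]
        ordered.to_csv(f"{prefix}_zscores_clustered.tsv", sep="\t",
                       float_format=_FLOAT_FMT)
        with open(f"{prefix}_row_tree.nwk", "w") as fh:
            fh.write(result.row_tree.to_newick() + "\n")
        with open(f"{prefix}_column_tree.nwk", "w") as fh:
            fh.write(result.column_tree.to_newick() + "\n")
        top_n = min(30, complete.shape[1])
        corr = codisruption_correlation(matrix, top_n=top_n)
        corr.to_csv(f"{prefix}_codisruption.tsv", sep="\t", float_format=_FLOAT_FMT)


def _write_baselines(cfg, seed_tables, collections, all_common, outdir: Path) -> None:
    from .baselines import (
        GeneSignificanceTable,
        cancer_gene_fraction,
        enrichment_table,
        gene_ranking_aggregated,
        load_census,
    )

    census = load_census(cfg.census)
    sig_tables = [
        GeneSignificanceTable.from_seed_table(t) for t in seed_tables.values()
        if t.has_q_values()
    ]
    if not sig_tables:
        log.warning("baselines skipped: no q-values in any seed table")
        return
    selected = gene_ranking_aggregated(sig_tables, top_fraction=0.05)
    universe = set().union(*(t.genes for t in sig_tables))
    for collection in collections:
        frame = enrichment_table(selected, collection, universe)
        frame.to_csv(
            outdir / f"{collection.source_label}_baseline_enrichment.tsv",
            sep="\t", float_format=_FLOAT_FMT,
        )
    rows = []
    for label, common in all_common.items():
        collection = next(c for c in collections if c.source_label == label)
        module = set()
        for name in common["pathway"]:
            module.update(collection[name].members)
        if not module:
            continue
        result = cancer_gene_fraction(
            module, census,
            gene_pool=collection.member_union(),
            n_controls=100, rng_seed=cfg.seed,
        )
        rows.append({
            "collection": label,
            "module_size": result["module_size"],
            "fraction": result["fraction"],
            "control_mean": result["control_mean"],
            "control_sd": result["control_sd"],
        })
    if rows:
        pd.DataFrame(rows).to_csv(
            outdir / "census_fractions.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
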