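# pathprop

Network-based analysis of pathway disruption by copy-number alterations.
Gene-level amplification/deletion scores are propagated over a
protein–protein interaction network by label propagation, pathway
activity is the mean propagated score of member genes, and disrupted
pathways are selected per cancer type with permutation-based empirical
p-values, Benjamini–Hochberg adjustment and rank filters. The package
also provides overrepresentation baselines (pooled/aggregated gene
ranking + hypergeometric tests), co-disruption pattern analysis
(Z-scores, complete-linkage clustering, correlation heat-map inputs),
per-pathway network views for visualization, and a synthetic-data module
that generates fully self-contained test instances with planted ground
truth.

## Method sketch

Given an undirected gene network with adjacency `G` and degree matrix
`D`, the propagation operator is `Gbar = D^-1/2 G D^-1/2`. With an
initial score vector `g` (average |log2 ratio| for seed genes, 0
elsewhere) and balance parameter `alpha` (default 0.5), the propagated
scores solve

```
g_tilde = (1 - alpha) (I - alpha Gbar)^-1 g
```

computed by a direct sparse solve, or equivalently by iterating
`g_t = (1 - alpha) g + alpha Gbar g_{t-1}` to convergence. A pathway's
activity in one cancer is the mean of `g_tilde` over its member genes
found in the network; a pathway is called disrupted in a cancer when its
permutation q-value passes the collection-specific FDR cutoff *and* its
activity ranks in the top fraction for that cancer. Commonly disrupted
pathways additionally recur in at least `min_cancer_types` cancers.

## Input formats

- **Network**: two-column tab-delimited edge list (or SIF); symbols are
  uppercased, self-loops and duplicate edges dropped; an optional node
  file retains isolated nodes.
- **Pathways**: standard GMT (`name<TAB>description<TAB>member...`).
- **Seed tables**: one TSV per cancer type with header
  `gene alteration avg_log2_ratio [q_value frequency arm_level]`,
  `alteration` in `{amp, del}`. Alternatively a gene × patient log2-ratio
  matrix plus amp/del gene lists (`averages_from_matrix`).
- **Cancer-gene reference**: plain text, one symbol per line.

## CLI

```bash
# generate a synthetic instance (network, GMT, per-cancer seed TSVs, manifest)
pathprop simulate --scenario direct --n-genes 2000 --n-pathways 200 \
    --n-cancers 16 --planted-cancers 12 --seed 1 --out demo/

# full pipeline: propagate, score, permutation significance, selection,
# pattern analysis; writes TSV matrices and a JSON run manifest
pathprop run-all --config demo/manifest.yaml --seed 1 \
    --permutations 1000 --mode both --out demo_results/

# single-cancer pieces
pathprop propagate --network demo/network.tsv --seed-table demo/seeds/CANCER_00.tsv --out act.tsv
pathprop score --network demo/network.tsv --seed-table demo/seeds/CANCER_00.tsv \
    --gmt demo/pathways.gmt --out scores.tsv

# selection / patterns / baselines / network views from written matrices
pathprop select --scores demo_results/synthetic_scores.tsv \
    --qvalues demo_results/synthetic_qvalues.tsv --out-prefix sel
pathprop patterns --scores demo_results/synthetic_scores.tsv --out-prefix pat
pathprop netview --network demo/network.tsv --gmt demo/pathways.gmt \
    --seed-table demo/seeds/CANCER_00.tsv --pathway PLANTED_000 --out-prefix view
```

Identical config + seed produces byte-identical score matrices and
manifests.

## Package layout

| module | contents |
| --- | --- |
| `pathprop.graph` | network loading/validation, normalized adjacency |
| `pathprop.seeds` | seed-table parsing, initial activity vectors |
| `pathprop.propagation` | closed-form and iterative propagation |
| `pathprop.scoring` | GMT parsing, pathway activity, matrix assembly |
| `pathprop.significance` | permutation nulls, empirical p, BH, selection |
| `pathprop.baselines` | pooled/aggregated ranking, hypergeometric tests, census fractions |
| `pathprop.patterns` | Z-scores, deterministic complete-linkage clustering, co-disruption |
| `pathprop.netview` | pathway neighborhood construction, SIF/GraphML export |
| `pathprop.simulate` | synthetic instances with planted truth, decoy pathways |
| `pathprop.pipeline`, `pathprop.cli` | orchestration and command line |
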