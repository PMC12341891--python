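# netstab

Robustness analysis of graph community structure under controlled
edge-rewiring perturbation.

Community-detection results are hard to trust without ground truth. `netstab`
quantifies how stable a detected partition is when a growing fraction of
edges is rewired (node and edge counts preserved), summarizing each method as
a *stability curve* — distance between the reference partition and the
partitions of perturbed graphs, per perturbation level. On top of the curves
it provides:

- **Method / parameter comparison** (`compare_methods`): several methods are
  run on the *same* perturbed graphs (paired design); the curve with the
  lowest trapezoidal AUC wins.
- **Validation against a null model** (`validate_vs_null`): the observed
  curve is compared with the curve of a degree-matched configuration-model
  random graph, via
  - a Gaussian-process Bayes-factor test (`gp_bayes_factor`; BF > 100 read
    as strong evidence the curves come from distinct processes), and
  - an interval-wise permutation test (`interval_wise_test`; one
    error-controlled adjusted p-value per perturbation level).
- **Single-cell adapter** (`knn_neighbors`, `snn_jaccard_graph`): builds the
  standard KNN / shared-nearest-neighbor Jaccard cell graph from a
  cells × PCs embedding, so clustering pipelines can be evaluated on their
  graphs; partitions export as `(cell_id, cluster)` CSV annotations.
- **Synthetic generators** (`sbm_graph`, `er_graph`,
  `gaussian_mixture_embedding`): planted ground truth for every test, no
  downloads.

Default perturbation grid: 12 levels, 5%…60% in 5% steps, 10 replicates per
level. Default stability measure: variation of information (nats, ≤ ln n);
NMI, adjusted Rand, and split-join are also available (similarities are
mapped to distances as 1 − value). All randomness flows through a
splittable `RandomState`: one seed gives bit-identical results for any
worker count (`n_jobs` parallelizes over perturbation levels).

## CLI

Everything is reachable through the `netstab` command. A typical synthetic
end-to-end run:

```sh
# 1) simulate a planted-partition graph
netstab simulate --kind sbm --blocks 50,50,50,50 --p-in 0.3 --p-out 0.01 \
    --seed 1 --out out/sbm

# 2) compare methods on it (paired perturbations, AUC ranking)
netstab compare --graph out/sbm.tsv --methods louvain,walktrap,labelprop \
    --seed 1 --out out/cmp
netstab rank --result out/cmp.json

# 3) validate the winner against a configuration-model null
netstab robust --graph out/sbm.tsv --method louvain --seed 1 --out out/rob
netstab test --result out/rob.json --kind gp  --seed 1 --out out/gp
netstab test --result out/rob.json --kind iwt --seed 1 --out out/iwt

# 4) plots (curve ribbons, optional AUC bars)
netstab plot --result out/cmp.json --out out/curves.png --auc-bars
```

Single-cell route: start from an embedding CSV (first column `cell_id`,
then coordinates):

```sh
netstab simulate --kind gmm --cells 300 --clusters 3 --seed 1 --out out/mix
netstab sc-graph --embedding out/mix.embedding.csv --k 15 \
    --out out/cells.graphml
netstab compare --graph out/cells.graphml --methods louvain,leiden \
    --seed 1 --out out/sc
```

Method specs take parameters inline, e.g. `leiden:resolution=0.5`; sweep a
parameter by listing several specs in `--methods` (or `method_grid` in the
API). Every analysis run writes `<out>.json` (full result, reloadable),
`<out>.csv` (long-format curves) and `<out>.log` (seed, grid, versions).
A flat `key=value` config file can supply defaults for any option:
`netstab --config run.cfg compare ...` (explicit flags win).

Graph formats: whitespace edge list (`u v [weight]`, `#` comments, a
single-token line declares an isolated node), GraphML, and symmetric
MatrixMarket `.mtx` adjacency (node ids are 1-based indices).

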