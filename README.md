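# planknet

Bipartite plankton co-occurrence networks: compositional correlation
inference, degree-preserving null models, stability (robustness and
vulnerability) analysis, and module–environment statistics — driven by a
synthetic plankton-community generator with known ground truth.

## What it does

Given phytoplankton and zooplankton density tables (two zooplankton size
fractions), the pipeline:

1. **`synthdata`** — generates synthetic communities: log-normal densities
   with planted cross-guild/cross-fraction associations, environmental
   coupling, site structure, zero inflation, and optional compositional
   closure; writes round-trippable TSV/JSON fixtures.
2. **`tables_io`** — data model, TSV/CSV readers with validation, the
   size-fraction intersection filter (only species caught in both fractions
   are retained), and sample alignment.
3. **`netinfer`** — correlations for compositional data via log-ratio
   variances and basis-variance estimation with iterative pair exclusion;
   column-permutation p-values; bipartite network construction at the
   |r| ≥ 0.3, p < 0.05 thresholds.
4. **`topology`** — network size, links, links per species, pairwise
   bipartite clustering, quantitative (Shannon) linkage density, and
   weighted connectance (= linkage density / size).
5. **`nulls`** — Maslov–Sneppen degree-preserving rewiring ensembles and
   one-sample t-tests of null distributions against empirical values.
6. **`stability`** — robustness under random guild-targeted node removal
   with secondary extinctions, robustness-vs-fraction regression slopes,
   curve permutation comparisons, global efficiency, node/network
   vulnerability, and dominant-taxon subnetwork extraction.
7. **`modules_env`** — greedy-modularity modules, Zi/Pi hub classification
   (thresholds 2.5 / 0.62), module eigenvalue (first PC) series, module–
   factor correlations with significance stars, preserved-module pairing
   across size fractions (≥ 50 % shared nodes), and connectivity-vs-
   significance Mantel tests.
8. **`cli`** — `planknet` command-line orchestration.

## CLI

```bash
# generate a synthetic fixture
planknet simulate runs/fixture --seed 1 --n-samples 120 --n-sites 6

# full pipeline from a YAML config
planknet run --config config.yaml

# standalone stages on saved intermediates
planknet infer runs/fixture runs/net --fraction smaller --seed 1
planknet topology runs/net/network.graphml --out runs/topology.json
planknet nulls runs/net/network.graphml --out runs/nulls.json
planknet stability runs/net/network.graphml --out-dir runs/stab
planknet modules runs/net/network.graphml --out runs/partition.tsv
planknet env runs/net/network.graphml runs/fixture --out runs/mantel.json
```

Example `config.yaml`:

```yaml
fixture_dir: runs/fixture
output_dir: runs/demo
seed: 1
network: {n_permutations: 100}
nulls: {n_networks: 1000}
stability: {f: 0.5, n_trials: 100, fractions: [0.1, 0.3, 0.5, 0.7, 0.9]}
mantel_permutations: 999
per_site: false
```

Identical config + seed reproduces every numeric output byte-for-byte.

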