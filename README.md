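# pdpmflow

Network-rewiring analysis for disease progression. Given per-stage
disease gene lists and a protein–protein interaction (PPI) edge list,
`pdpmflow` builds one subnetwork per disease stage, detects topological
modules in each, pairs modules across stages that share genes, scores
how strongly each pair's internal structure changed with an
entropy-weighted distance (the **K-value**), and selects the most
strongly rewired pairs — **paired disease progression modules (PDPMs)**
— with a golden-section (61.8 %) threshold. Optional downstream steps
summarise pathway enrichment of PDPM genes and gain/loss proportions of
structural variants hitting them.

The underlying idea: as a disease progresses through stages, the genes
driving it do not merely change identity — their interaction modules
split, merge and restructure. Module pairs whose topology changed most
between stages are candidates for the progression mechanism.

## Model

For two stage networks $G_a$, $G_b$ with module partitions, every pair
of modules $(M_i, M_j)$, one per stage, sharing at least one gene is a
*module reconstruction pair* (MRP). Each module is described by four
topology indicators measured on its induced subgraph: node count, edge
count, average neighbour count, and characteristic path length (mean
shortest-path length over connected pairs). Scoring proceeds in four
steps:

1. **Normalisation.** Indicator values of all modules entering a
   comparison are min–max rescaled to $[0,1]$:
   $D_{ik} = (f_{ik} - f_k^{\min}) / (f_k^{\max} - f_k^{\min})$.
2. **Relative distance.** For a pair $(i,j)$, each indicator's share of
   the squared distance is
   $d_k = (D_{ik} - D_{jk})^2 / \sum_l (D_{il} - D_{jl})^2$, so
   $\sum_k d_k = 1$. A pair with identical profiles (e.g. a module
   conserved under one shared interactome) is degenerate: $d = 0$.
3. **Entropy weights.** Indicator weights come from the entropy-weight
   method on the normalised module × indicator matrix:
   $p_{ik} = D_{ik} / \sum_i D_{ik}$,
   $e_k = -\tfrac{1}{\ln m}\sum_i p_{ik}\ln p_{ik}$,
   $w_k = (1 - e_k) / \sum_l (1 - e_l)$ — indicators that differentiate
   modules more get more weight.
4. **K-value.** $K_{ij} = \sqrt{\sum_k w_k d_k}$. With uniform weights
   every non-identical pair scores exactly $0.5$; informative weights
   move pairs above or below that anchor.

K-values of all comparisons are pooled, min–max rescaled to 0–100 %, and
pairs strictly above 61.8 % are called PDPMs. This corresponds to a
single raw-K threshold (reported as the largest K among non-selected
pairs).

Module detection runs three methods — MCODE (k-core-weighted
seed-and-grow), Markov clustering (MCL), and greedy modularity
communities — and keeps the partition with minimum Shannon entropy of
its module-size distribution.

## Quick start

The package ships a generator for fully synthetic inputs with known
ground truth, so the whole pipeline can be exercised without any
external data:

```python
from pdpmflow.synthetic import ScenarioConfig, simulate_scenario

cfg = ScenarioConfig(
    n_modules=3, module_size=8, p_in=0.9, p_out=0.02, n_stages=3,
    plan=({"op": "conserve", "sources": [0]},
          {"op": "split", "sources": [1], "ways": 2},
          {"op": "conserve", "sources": [2], "churn": 0.25}),
    seed=42,
)
simulate_scenario(cfg).write("inputs")
```

Then run the full analysis from a YAML config:

```yaml
# config.yaml
stages: [A, B, C]
gene_lists:
  A: inputs/stage_A.genes.txt
  B: inputs/stage_B.genes.txt
  C: inputs/stage_C.genes.txt
edge_list:
  A: inputs/stage_A.edges.tsv
  B: inputs/stage_B.edges.tsv
  C: inputs/stage_C.edges.tsv
output_dir: results
```

```text
$ pdpmflow run-all --config config.yaml
{
  "implied_k_threshold": 0.0,
  "methods": {
    "A": "mcode",
    "B": "mcode",
    "C": "mcode"
  },
  "n_mrps": 7,
  "n_pdpms": 2,
  ...
}
```

(Output above is the actual headline block for seed 42.) `results/`
then contains per-stage networks and module tables, per-comparison
weight/distance/K tables, `mrps.tsv`, `pdpms.tsv` and a JSON stage
report:

```text
$ column -t results/pdpms.tsv
stage  module_a  module_b  K             k_percent   is_pdpm
A-B    A1        B1        0             0.000000    false
A-B    A2        B2        0             0.000000    false
A-B    A3        B3        0             0.000000    false
A-C    A1        C2        0.4329425861  100.000000  true
A-C    A2        C1        0             0.000000    false
B-C    B1        C2        0.4329425861  100.000000  true
B-C    B2        C1        0             0.000000    false
```

Module pairs whose induced subgraphs are identical under the shared
interactome score K = 0; the structurally rewired pairs stand out and
are selected.

Each stage is also available as its own subcommand (`build-net`,
`modules`, `mrp`, `kvalue`, `pdpm`, `enrich`, `sv`, `simulate`); chaining
them reproduces `run-all` exactly (this is tested).

For real data, the expected inputs are: one gene-symbol list per stage
(plain text or CSV), a STRING-style edge list
(`protein1 protein2 combined_score`, optional `--min-score` filter), and
optionally a GMT pathway collection and a DGV-dialect structural-variant
table.

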