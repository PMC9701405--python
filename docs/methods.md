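# Methods

This document specifies the algorithms, defaults and numerical choices
implemented in `pdpmflow`, and the design of the synthetic-data
generator used for validation.

## 1. Inputs and network construction

- **Gene lists** (`network_io.read_gene_list`): one symbol per line, or
  a CSV column via `gene_column`. Symbols are upper-cased and
  deduplicated preserving first occurrence. Empty lists are an error.
- **Edge lists** (`read_edge_list`): whitespace/tab-separated
  `protein1 protein2 combined_score` (STRING dialect). A header row is
  auto-detected. Reverse duplicates collapse to one undirected edge
  keeping the maximum score; self-loops are dropped; `min_score`
  filters on the third column (STRING scores are 0–1000; 400 = medium
  confidence).
- **Disease subnetworks** (`build_disease_network`): the induced
  subgraph of the interactome on the gene list. Genes absent from the
  interactome, and genes present but isolated within the induced
  subgraph, are excluded (counts logged). An empty intersection is an
  error.
- **Topology statistics** (`network_stats`): density `2E / (N(N-1))`,
  average clustering coefficient, Freeman degree centralization,
  average neighbour count `2E/N`, and characteristic path length (CPL)
  averaged over *connected* node pairs only, so disconnected networks
  get a finite CPL rather than infinity.

## 2. Module detection and selection

Three detectors run on each stage network; the partition with minimum
Shannon entropy of its module-size distribution wins.

**MCODE** (`mcode`, defaults `degree_cutoff=2`, `node_score_cutoff=0.2`,
`k_core=2`, `max_depth=100`, `min_module_nodes=4`): each vertex is
weighted by `k * density` of the highest k-core of its closed
neighbourhood (0 if its degree is below `degree_cutoff`). Complexes
grow breadth-first from the highest-weight unused seed, admitting
neighbours whose weight is at least `seed_weight * (1 -
node_score_cutoff)`, to depth `max_depth`. Grown complexes below
`min_module_nodes` are discarded but their nodes stay consumed.
Modules are labelled `<LABEL><rank>` by descending mean vertex weight.
Note a consequence of the rule as stated: two equally dense cliques
joined by a single bridge merge into one complex, because every vertex
(bridge endpoints included) carries the same weight and passes the
threshold. This is the faithful behaviour of the growth rule and is
what the tests assert, cross-checked against an independent brute-force
transcription.

**MCL** (`mcl`, `inflation=2.0`, expansion power 2): self-loops of
weight 1 are added, the adjacency matrix is column-normalised, and
expansion/inflation alternate to convergence; clusters are read off
attractor rows. **Greedy modularity** (`community`) wraps
`networkx.algorithms.community.greedy_modularity_communities`.

**Partition entropy** (`partition_entropy`): Shannon entropy of the
module-size distribution over *clustered* nodes only
(`H = -Σ (n_i/n) ln(n_i/n)`). A partition with no modules gets `+inf`
(so it can never win selection); single-module partitions get 0, which
correctly encodes "most concentrated". Ties break in the fixed order
mcode > community > mcl.

## 3. MRPs and rewiring classes

Two modules from consecutive (or any ordered pair of) stage networks
sharing ≥ 1 gene form a module reconstruction pair (MRP;
`mrp.find_mrps`). `classify_rewiring` labels earlier modules with ≥ 2
forward partners as *split*, later modules with ≥ 2 contributors as
*merge* (their contributors get no separate call), one-to-one pairs as
*conserved*, and unmatched modules as *lost*/*novel*.

## 4. K-value scoring

For every module entering a comparison, four indicators are measured on
its induced subgraph: node count, edge count, average neighbour count,
CPL. Then:

1. **Min–max normalisation**, pooled over all modules of the comparison
   (both stages together), per indicator. Default orientation is
   "benefit" (`D = (f - f_min)/(f_max - f_min)`); per-indicator "cost"
   orientation (`1 - D`) is configurable. A constant indicator
   normalises to 0 for every module.
2. **Relative squared distance** per pair:
   `d_k = (D_ak - D_bk)² / Σ_l (D_al - D_bl)²`, so `Σ d_k = 1`.
   *Degenerate rule*: if the profiles are identical within `1e-9`
   (squared-difference sum below tolerance), `d = 0` and `K = 0` — the
   pair is structurally unchanged.
3. **Entropy weights** from the normalised module × indicator matrix:
   `p_ik = D_ik / Σ_i D_ik`, `e_k = -(1/ln m) Σ_i p_ik ln p_ik`,
   `w_k = (1 - e_k) / Σ_l (1 - e_l)`. An all-constant column gets
   `e = 1`, hence weight 0; if every column is constant, weights fall
   back to uniform. `weight_source="distances"` instead derives weights
   from the matrix of per-pair distance vectors.
4. **K** `= sqrt(Σ_k w_k d_k)`, in `[0, sqrt(max_k w_k)] ⊆ [0, 1]`.

Algebraic consequences, all tested: with uniform weights every
non-identical pair scores exactly 0.5; K is symmetric in the two
modules; the distance vector is invariant under the cost/benefit flip
`x → 1 - x`, so K is orientation-insensitive under
`weight_source="distances"` — but *not* in general under
profile-derived weights, because the flip changes the `p_ik` shares.

Modules smaller than `min_module_nodes` (default 4) are excluded from
scoring.

## 5. PDPM selection

All K-values are pooled (default `pooling="global"`; `"per-stage"`
rescales each comparison separately), min–max rescaled to 0–100 %, and
pairs strictly above the golden-section cutoff (61.8 %) are selected.
Global pooling makes the selection equivalent to one raw-K threshold,
reported as the largest K among non-selected pairs (the "K > t" form).
The stage report ranks stage comparisons by ascending mean PDPM K —
lower mean K means the two stages' modules are structurally closer.

A degenerate K distribution (all equal) has no range to divide and is
an error rather than a silent all-or-nothing selection.

## 6. Enrichment and structural variants (optional)

**ORA** (`enrichment.ora`): upper-tail hypergeometric p-value
(`scipy.stats.hypergeom.sf(k-1, N, K_term, n)`), fold enrichment
`(k/n) / (K_term/N)`; a term passes when `k ≥ 3`, `p < 0.01` and
`fold ≥ 1.5` (the usual web-service defaults). Background defaults to
the union of collection genes. Benjamini–Hochberg q-values are optional
and do not change the pass rule.

**Structural variants** (`sv_analysis`): DGV-dialect TSVs are filtered
to subtypes {complex, inversion, loss, gain}; rows with missing
accession/coordinates/genes are dropped with a logged count. Group
summaries deduplicate by accession across the gene group, so one SV
spanning several query genes counts once; per-gene tallies (which do
double-count such SVs) are reported alongside. Percentages are over
retained subtypes and sum to 100.

## 7. Synthetic-data generator

`synthetic.simulate_scenario` plants module memberships for every stage
first (applying a per-transition plan of `conserve` / `split` / `merge`
/ `novel` operations, each with an optional membership-churn fraction),
then samples **one master interactome**: node pairs that share a module
in *any* stage get an edge with probability `p_in`, all other pairs
`p_out`. Each stage network is the induced subgraph of this master
graph on that stage's gene universe.

This single-interactome design is deliberate. Real stage networks all
derive from one PPI database, so a module conserved between stages
induces the *identical* subgraph in both — and correctly scores K = 0
under the degenerate rule. Sampling each stage's edges independently
instead injects pure sampling noise into conserved pairs; because the
relative-distance normalisation (`Σ d = 1`) discards difference
magnitude, that noise is indistinguishable from genuine rewiring and
destroys the conserved/rewired K separation (measured: ranking success
collapses to ≈ 50 %). What the generator therefore does **not**
emulate: stage-specific measurement noise in the interactome itself,
directed or weighted rewiring, or gradual edge-probability drift — only
membership-level rewiring on a fixed interaction substrate.

Gene symbols are synthesized (`G0001`, …); no real identifiers appear.
All draws come from `numpy.random.default_rng(seed)`, so outputs are
byte-identical across reruns. Companion generators produce gene lists
with exact three-set Venn region counts, GMT collections with a planted
common term core, and DGV-dialect variant tables with exact per-gene
subtype counts plus malformed decoy rows.

The standard power scenario (`power_scenario_config`) uses 4 modules ×
10 nodes, `p_in = 0.85`, `p_out = 0.02`, with one conserved module, one
2-way split and one merge absorbing 30 % churn. Problem sizes here are
the package's own validation choice: large enough for stable topology
indicators, small enough for a 100-seed sweep in seconds.

## 8. Numerical choices and limitations

- Degenerate-pair tolerance `1e-9` on the squared-difference sum:
  induced-subgraph-identical modules give exact zeros, so any small
  positive tolerance only guards against float noise in the min–max
  step.
- `Σ d = 1` is magnitude-blind by construction: the distance vector
  captures *which* indicators changed, not *how much*. Two pairs with
  proportional indicator differences of very different sizes get the
  same d, and hence the same K under shared weights. The degenerate
  K = 0 rule is what separates "unchanged" from "changed"; among
  changed pairs, K ranks the *pattern* of change weighted by indicator
  informativeness. Interpret K comparatively within a run, not as an
  absolute effect size.
- Entropy weights depend on the full module set entering a comparison:
  adding or removing modules changes every pair's K. Tables therefore
  always record the weight vector next to the K-values.
- CPL over connected pairs only: a module that fragments between stages
  can *decrease* its CPL; the node/edge indicators compensate, but CPL
  alone should not be read as compactness.
- MCODE keeps dense cores only; peripheral module members are routinely
  left unclustered. Coverage-style validation of planted modules uses
  the community detector for this reason.
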