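# Methods

## Model and screening procedure

The screen treats the cell's signaling system as an undirected simple
graph over gene symbols. Its single structural functional is the average
shortest path length D = Σ_{i>j} d_ij / (N(N−1)/2). Because node removal
can disconnect the graph — where the formula's denominator is no longer
meaningful — D is computed as the mean hop distance over *reachable*
unordered pairs, matching the usual convention of graph libraries; a
strict mode raises instead. On a connected graph the two definitions
coincide exactly.

For a candidate pair (m cancer, n non-cancer) the stability score is
S = (2·D_{m,n} − D_m − D_n)/D_0. Writing it as
[(D_{m,n} − D_m) + (D_{m,n} − D_n)]/D_0 shows what it measures: the extra
stretching attributable to the *joint* knockout beyond each single
knockout. A hub whose single removal already lengthens paths contributes
to D_m and is thereby discounted; only genuinely synergistic pairs score
high.

The null model is degree-preserving double-edge-swap randomization
(10 attempted swaps per edge by default; swaps creating self-loops or
parallel edges are rejected, so the degree sequence is preserved exactly
and the graph stays simple). The empirical p-value uses the strict
inequality p = #(S_random > S_obs)/n_random with no pseudocount, exactly
as the score's definition demands; an optional (r+1)/(n+1) correction flag
exists because p = 0 is statistically awkward, but it is off by default.
Two consequences are documented rather than hidden: on a graph whose
degree sequence admits no rewiring (e.g. a complete graph) all null scores
tie the observed one and every pair gets p = 0; and p-values at
n_random = 100 are multiples of 0.01.

Each randomized network is scored with its *own* average path length as
D_0 — the self-consistent application of the score to that network. A
flag switches to reusing the observed D_0 for sensitivity analysis. Per
network, D_m is cached per cancer gene and D_n per non-cancer gene (both
are pair-independent); the cached path is contract-tested against the
uncached single-pair evaluation.

The three filters after scoring:

- **Distance.** Pairs farther apart than a threshold are dropped. In
  `auto` mode the threshold is ⌊mean pair distance⌋ over all candidate
  pairs (a mean of 2.90 gives 2); reading the rule as "strictly below the
  mean" is the other defensible choice, so an explicit integer threshold
  is also accepted.
- **Frequency.** For every (cancer, non-cancer) pair, each non-cancer gene
  interior to at least one shortest path between them is credited once
  (endpoints excluded; a gene is never credited twice for one pair however
  many shortest paths it sits on — the count is "pairs served", not
  betweenness). The screen keeps the shortest count-descending prefix of
  genes holding `mass_fraction` (default 0.5) of the total credit.
- **Function.** Hypergeometric upper-tail enrichment of every gene set
  against the surviving genes, background = all network genes,
  Benjamini–Hochberg across sets; a pair survives only if *both* genes
  belong to some set with q < 0.05. The both-genes rule is what makes this
  a pair filter rather than a gene filter.

Validation channels: (1) canonical unordered pair overlap with an SL
reference table; (2) drug sensitivity — a target is supported when a cell
line mutated in one of its SL partners is sensitive (log-IC50 < 0) to a
drug hitting the target (a looser target-only mode exists for comparison);
(3) literature — per gene, P[at least x of its K studies are
context-relevant] under a hypergeometric null with global study counts
(M relevant of N total), evaluated in log space so PubMed-scale counts are
safe; a gene passes when both the cancer and the SL context are significant
at 0.05. Triple-validated targets are the intersection of the channels and
are invariant to evaluation order.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `top_fraction` | 0.30 | fraction of non-cancer genes (by traversal frequency) paired with cancer genes |
| `mass_fraction` | 0.50 | cumulative traversal mass kept by the frequency filter |
| `n_random` | 1000 | null-ensemble size (100 in the synthetic bundle's config) |
| `alpha_network` | 0.05 | empirical-p cutoff of the network screen |
| `distance_mode` | auto | ⌊mean pair distance⌋, or an explicit hop count |
| `alpha_enrich` | 0.05 | BH q cutoff of the function screen |
| `ic50_cut` | 0 | log-IC50 (natural-log µM) sensitivity threshold |
| `swaps_per_edge` | 10 | attempted double edge swaps per edge |

## Synthetic fixtures

`slnet.synthfix` generates the test substrate: a Barabási–Albert graph
(heavy-tailed, like curated signaling networks; Erdős–Rényi is kept for
null-calibration because it has no structure to find), gene symbols
`G000…`, a uniformly random cancer subset. Planted pairs are built by
carving, per pair, a six-node satellite group that connects to the rest of
the network only through the planted cancer gene m, the planted non-cancer
gene n (a high-degree hub, so it also survives the frequency screens) and
one long backup route that keeps the graph connected when both are
removed. Companion tables follow the planted truth: one gene set holds all
planted genes (plus random decoy sets), drug records cover 80% of planted
non-cancer genes, the SL reference holds 60% of planted pairs plus decoys,
sensitivity rows are negative-log-IC50 for planted (partner, target)
combinations and non-negative for decoys, and literature counts give
planted genes an elevated relevant fraction (0.4 cancer / 0.3 SL of K
studies against background rates of 5% and 0.5%). One global seed derives
independent per-component sub-seeds (CRC32 of the component name), so
adding a component never perturbs another's draw.

The default bundle is 200 nodes, mean degree ~6, 20 cancer genes, 5
planted pairs, screened against 100 randomizations. At seed 1 the five
planted pairs rank 1–5 of 1080 by (p, −S) (all p = 0) and the final SL
list is exactly the planted set; the recovery test pins ≥ 80% so that the
check verifies the construction, not one lucky draw. What passing shows:
the pipeline detects strong bridge-type synthetic lethality planted in a
sparse scale-free graph. What it does not show: performance on real
signaling networks, whose SL signal is weaker, whose annotations are
noisy, and whose gene sets are not built around the answer.

## Numerical choices

- Distances are computed by batched breadth-first search: all sources at
  once, each BFS ring one float32 matrix product (BLAS), for graphs up to
  1500 nodes; larger graphs use scipy's sparse Dijkstra. Both routes are
  verified against a pure-Python Floyd–Warshall oracle. Distances are
  integers, so means in float64 are exact to representation; no tolerance
  is needed beyond float comparison in tests.
- Ties in every ranking (frequency, top-fraction, cumulative cutoff) break
  lexicographically by symbol; top-fraction size uses the ceiling. Output
  files sort by their primary key, which with fixed seeds makes every
  artifact byte-reproducible.
- Degenerate evaluations (a removal leaving no reachable pair) flag the
  record rather than raising mid-screen; degenerate pairs are excluded
  downstream and counted in the manifest.
- Gene symbols are uppercased and whitespace-stripped; no alias mapping is
  attempted (that is data preparation, and silently "fixing" symbols would
  be worse than failing visibly).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the end-to-end screen at the
default bundle size (1080 pairs × 101 networks of 200 nodes), the
null-uniformity check on a 100-node Erdős–Rényi graph (50 pairs × 200
randomizations, Kolmogorov–Smirnov at α = 0.01), degree-preservation over
1000 (tests) / 200 (script) randomizations, and byte-determinism on a
100-node bundle with 10 randomizations. These sizes were chosen as the
smallest at which every effect the checks assert is unambiguous.

## Known limitations

- The screen is O(pairs × n_random) average-path-length evaluations; a
  full curated human signaling network (~6000 nodes, ~500k pairs, 1000
  randomizations) is a cluster-scale computation, not a laptop run. The engine's caching makes
  the per-network cost |cancer| + |non-cancer| + |pairs| BFS sweeps.
- The reachable-pairs convention makes D discontinuous when a removal
  splits off large components; records where that happens are still valid
  scores but deserve inspection (the `Dm`/`Dn`/`Dmn` columns are kept in
  every output for exactly this reason).
- Empirical p-values are granular at 1/n_random and the strict-inequality
  definition maps total ties to p = 0 (see above).
- The enrichment background defaults to all network genes; a
  curation-biased background (as proprietary annotation services use)
  will give different, not necessarily worse, q-values.
- The literature channel consumes prepared count tables; deriving K and x
  requires a text-mining pipeline that is out of scope here.
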