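# Methods

## The workflow

`mircover` asks whether a set of disease-associated miRNAs co-regulates a
common part of the signaling-pathway landscape in a given tissue, using
only three public-style resources: a validated miRNA→target catalog, a
tissue expression atlas, and a scored protein–protein interaction (PPI)
network, plus a pathway gene-set collection.

For each miRNA *m* with target set *T(m)*:

1. **Expression filter.** Keep targets expressed in the tissue,
   `T'(m) = {g ∈ T(m) : level(g) ≥ τ}` with τ = 1 nTPM by default.
2. **Network construction.** Take the vertex-induced subgraph of the
   high-confidence PPI (combined score ≥ 0.9, inclusive) on `T'(m)`;
   targets absent from the PPI stay as isolated nodes.
3. **LCC and centralities.** Extract the largest connected component
   (LCC); for every node compute normalized degree `deg(v)/(n−1)` and
   pair-normalized betweenness
   `2/((n−1)(n−2)) · Σ_{s≠v≠t} σ_st(v)/σ_st`, and their sum
   ("combined", range [0, 2]).
4. **Key-gene extraction.** Remove nodes in order of decreasing combined
   centrality (ties: lexicographic gene symbol). The curve S(k) — LCC
   cardinality of the surviving graph after k removals — is
   non-increasing; the *key genes* are the removal prefix up to the
   plateau point p\*.
5. **Overrepresentation.** Test the key genes against every pathway with
   the one-sided hypergeometric (Fisher exact upper-tail) test in a
   universe of pathway-annotated, tissue-expressed genes;
   Benjamini–Hochberg across pathways per miRNA; gate at q < 0.05.
6. **Bigraph and greedy cover.** Connect miRNA *m* to pathway *P* when
   *P* is significant for *m*. If at least two miRNAs are connected,
   repeatedly extract *modules*: all pathways tied at the iteration's
   maximal coverage c\* (number of still-uncovered adjacent miRNAs),
   together with the union of their miRNA neighborhoods; remove both and
   iterate (default two iterations). If no two miRNAs share a pathway,
   the same search runs on a miRNA–key-gene bigraph instead.
7. **Monte Carlo significance.** Compare the observed bigraph against
   random same-size miRNA sets drawn from the whole catalog (eligibility:
   the miRNA's network has an LCC of ≥ 2 nodes). Two right-tailed
   empirical tests with the +1 correction
   `p = (1 + #{null ≥ observed}) / (iterations + 1)`:
   the **degree-shift test** (default statistic: mean pathway-node
   degree; max degree and skewness are selectable) and the
   **module-coverage test** (statistic: iteration-1 maximal coverage c\*).
8. **Robustness.** For networks with |LCC| > 50, eject random non-key
   nodes cumulatively in nine steps of 10% of the original non-key count,
   re-extract key genes after each step, and record the overlap fraction
   |test ∩ true| / |test| and cardinality ratio |test| / |true|.

## Design choices where the procedure was open

**Static centrality ranking.** Centralities are computed once on the
intact LCC, not recomputed after each removal. A static ranking makes the
removal order a pure function of the input graph and keeps the peel
O(n·m) overall.

**Plateau criterion.** The decay curve's plateau is located with a knee
rule: p\* maximizes the vertical distance between S(k) and the chord from
(0, S(0)) to (m, S(m)); a linear or constant curve yields p\* = 1. A
windowed alternative (first k from which the curve stays constant for
`window` steps) is available via `plateau_strategy="window"` for
sensitivity analysis.

**Tie handling.** Equal combined centralities break lexicographically by
gene symbol; tied maximal-coverage pathways all enter the module and
their miRNA neighborhoods need not coincide (the module covers the
union). Both rules make every result bit-reproducible.

**Coverage statistic = c\*, not the tie union.** In sparse bigraphs many
pathways can tie at a small c\* with disjoint neighborhoods, so the
union-of-ties size can be large without any single pathway being shared
by more than a few miRNAs. The Monte Carlo coverage statistic therefore
uses c\* — the largest number of miRNAs linked to one pathway — which is
the co-regulation signal the test is after. For a genuinely shared module
the two definitions coincide.

**Memoized null pipeline.** Per-miRNA results (network, LCC, key genes,
enrichment, significant set) are deterministic and independent of which
random set a miRNA is drawn into, so the pipeline context caches them;
each Monte Carlo iteration then costs only sampling plus bigraph
assembly. This is an exact optimization, not an approximation.

**Significance gate.** The bigraph edge gate defaults to the
FDR-adjusted q < 0.05 (configurable to raw p via `gate="p"`); a binomial
overrepresentation variant is available behind `method="binomial"`.

**Universe.** The enrichment universe defaults to pathway-annotated ∩
tissue-expressed genes, matching the restriction of the whole analysis to
expressed targets; `universe="collection"` drops the expression
intersection.

**Score threshold.** Interaction filtering is inclusive (score ≥ 0.9) and
`min_score` is exposed; a 0–1000 integer score column is auto-detected
and rescaled. Duplicate edge rows keep the maximum score; self-loops are
dropped.

**Cumulative ejection.** Within one robustness replicate the exclusion
set grows monotonically across the nine steps (step s has removed s·10%
of the original non-key nodes); replicates use fresh randomness.

## The synthetic data generator

The generator (`synthetic_data`) emits the four input files plus a
ground-truth manifest. Its defaults are the reference study conditions
used throughout the tests and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| `n_mirnas` / `n_background_mirnas` | 12 / 50 | query set; catalog pool for null draws |
| `targets_per_mirna` | 60–200 | validated targets per miRNA |
| `n_genes` | 800 | gene pool |
| `expressed_fraction` | 0.55 | genes ≥ 1 nTPM in the tissue |
| `graph_model` | truncated scale-free | power-law degrees (exponent 2.5) capped at 30, plus a rich-club layer (extra edges among the top 150 genes, p = 0.04) |
| `decoy_edge_fraction` | 0.3 | sub-threshold edges the reader must drop |
| `n_pathways`, `pathway_size` | 300, 10–40 | neighborhood-grown gene sets, 20% membership noise |
| `own_pathways_per_mirna` | 3–5 | pathways each miRNA genuinely regulates |
| `pathway_coverage` | 0.7 | fraction of a regulated pathway targeted |
| planted module | 3 pathways, 8 of 12 miRNAs | connected 14-gene core complex, embedding strength 1.0 |

Three structural features are essential and deliberately emulate real
data:

* **Truncated scale-free topology.** An unbounded preferential-attachment
  tail puts the same few super-hubs at the top of every induced network's
  centrality ranking, which erases miRNA-specific signal. Real
  high-confidence PPI subnetworks are scale-free in the body but no
  single protein dominates every neighborhood. Plain Barabási–Albert and
  Erdős–Rényi topologies remain available via `graph_model`.
* **Pathways as network neighborhoods.** Each pathway grows from a
  distinct anchor gene along high-confidence edges. Gene sets whose
  members do not interact would never intersect centrality-selected key
  genes, leaving every enrichment test empty.
* **Per-miRNA functional coherence.** Every miRNA targets ~70% of a few
  pathways of its own choosing plus a uniform background. Chance overlap
  alone cannot produce BH-significant enrichment at any useful rate, so
  a null in which miRNAs have no real pathway structure is degenerate
  (all empirical p-values equal 1). Which pathways a miRNA regulates is
  independent across miRNAs, so *sharing* remains purely random under the
  null — exactly what the Monte Carlo tests resample.

Planting removes the randomness of the coherence mechanism for the
chosen miRNAs: their regulated pathways are the planted ones, which are
overlapping supersets of a reserved, internally connected core complex;
each planted miRNA also targets a few expressed PPI neighbors of every
core gene (satellites), keeping the core at the top of the induced
centrality ranking. Planted and unplanted target sets have the same
structure and size, so the planted signal is the sharing itself, not
network size. At `embedding_strength=1.0` the full core is targeted;
recovery degrades to chance as the strength approaches 0.

What the generator does **not** emulate: realistic expression magnitudes
(only threshold crossing matters), directed or weighted signaling,
pathway hierarchies, and miRNA–target interaction strengths. Passing
tests on these data therefore demonstrate the correctness and internal
consistency of the algorithms under scale-free-like conditions, not the
biological validity of any particular real-data finding.

## Numerical and degenerate-input conventions

* Hypergeometric tails come from `scipy.stats.hypergeom.sf(k−1, N, K, n)`
  (exact to double precision; validated against rational-arithmetic
  summation in the tests); BH adjustment wraps
  `statsmodels.stats.multitest.multipletests(method="fdr_bh")`.
* Empty graphs yield an empty LCC with a warning; LCCs with fewer than
  two nodes are ineligible for extraction and such miRNAs drop out of
  eligibility for Monte Carlo draws.
* Component-size and centrality ties always break by lexicographic gene
  symbol, so all outputs are deterministic; re-running a pipeline with
  the same inputs and seed reproduces every artifact byte for byte.
* Empirical p-values can never be 0 (+1 correction) and ties count
  toward the tail, which makes the tests slightly conservative when the
  statistic is discrete.
* Percent columns in the run summary round half away from zero to whole
  percent.

## Problem sizes used by the tests and the acceptance script

Simulation scales were chosen so the whole suite runs on a single CPU in
a few minutes: the robustness ensemble uses 50 (tests) or 15 (script)
scale-free networks of 300 nodes with one ejection trajectory each;
planted-module recovery uses 50 (tests) or 25 (script) generated
datasets; Monte Carlo tests run 1,000 iterations; the null-calibration
study uses 200 (tests) or 100 (script) generator runs at 199 iterations
each. The memoized context makes each null iteration O(catalog lookup),
so iteration counts can be raised freely (the `mc_iterations`
config default for real analyses is 10,000).

## Known limitations

* The plateau index, and hence the key-gene count, is sensitive to
  cliff-shaped decay curves; the windowed strategy is provided to probe
  this sensitivity.
* The greedy cover is a (1 + ln n)-approximation to minimum set cover;
  exact covers are out of scope.
* Betweenness uses unweighted shortest paths; interaction scores act only
  as an edge filter.
* The degree-shift statistic is a scalar summary of the bigraph degree
  distribution; with very sparse bigraphs its discreteness makes the
  empirical p conservative.
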