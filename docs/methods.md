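# Methods

## Model and assumptions

`pbmoo` treats signalling inference as constrained combinatorial
optimisation on a PPI network. Three modelling assumptions drive the
design:

1. **Loop motifs mark signalling-dense regions.** Triangles and squares
   (the only simple-cycle shapes on ≤ 4 vertices) are over-represented in
   PPI networks relative to degree-matched random graphs, and
   preferentially sit in cancer and related signalling pathways. Merging
   overlapping loop instances into motif clusters, and keeping only
   clusters that significantly bridge a chosen pathway pair, yields a
   small, signalling-enriched search space (the *bridge*) instead of the
   full network.
2. **Differential expression is evidence of involvement.** Each
   protein's node cost is its DES — the two-sided equal-variance
   Student's t-test P-value between conditions, averaged over the
   datasets measuring it. A path of low-P proteins is a path supported
   by the perturbation experiment.
3. **Paths are short.** Since the bridge is assembled from ≤ 4-vertex
   loops, plausible paths span 2–7 proteins; the objective
   Σ xᵢ·DESᵢ + λ·Σ xᵢ is minimised subject to that bound. λ trades
   evidence against parsimony; the default λ = 0 imposes no length
   pressure beyond the hard bound, so all supported routes surface.

The network is undirected throughout; ligand→signature direction is a
reporting convention, not a graph property. No multiple-testing
correction is applied to the DES P-values: they act as relative costs,
not as hypothesis tests.

## Algorithmic choices

**Canonical classification.** A connected k-vertex subgraph (k ∈ {3,4})
is labelled by the minimum, over all k! vertex permutations, of its
upper-triangle adjacency bitstring. This gives 2 classes for k = 3 and 6
for k = 4, named by shape (path3, triangle; star, path4, triangle-tail,
square, diamond, clique4). The IDs are internal; external motif-tool IDs
depend on their own labelling conventions and are not reproduced.

**Census statistics.** Frequencies are normalised per network (class
count / total connected k-subgraphs of that network), so they sum to 1.
The null is `n_random` networks produced by double-edge swaps
(`swaps_per_edge × |E|` successful swaps, default 10, n_random default
100; both configurable). Z = (f_obs − mean f_null)/sd with the population
sd over null draws; the empirical P-value is the one-sided
#(null count ≥ observed count)/n_random, so enriched shapes get positive
Z and small p. When sd = 0, Z is defined as 0 and the empirical p is
still reported — this preserves information in the fully degenerate case
(e.g. a class that never occurs anywhere gets z = 0, p = 1).

**Swap rejection.** Proposed swaps that would create a self-loop or a
parallel edge are rejected and retried; attempts are capped at 20× the
requested swaps so graphs with no valid swap (a lone triangle) return
unchanged rather than looping forever.

**RAND-ESU.** Each depth d of the ESU enumeration tree is traversed with
probability p_d; surviving leaves are weighted by 1/Πp_d, which makes
the estimator exactly unbiased and reduces to exact enumeration at unit
probabilities.

**Squares are cycles, not induced subgraphs.** A "square" is any
distinct 4-cycle, including chorded ones: a diamond carries one, K₄
carries three. This reads the loop shape as the cycle pattern; the
alternative (chordless induced C₄ only) would discard exactly the
densest loop regions the method is trying to keep.

**Cluster merging is transitive.** Two loop instances sharing ≥ 1
protein belong to one cluster, and sharing chains: clusters are the
connected components of the instance-overlap graph. Center points are
proteins on ≥ 2 instances of their cluster; a cluster is identified by
its lexicographically smallest center point (smallest member for
single-instance clusters, which are retained — sharing describes
merging, not admission).

**Bridging rule.** A cluster lies "between" P₁ and P₂ iff it intersects
both. This is the weakest reading consistent with linking the two sets
and is isolated in one predicate (`bridge._bridges`) so stricter rules
can be swapped in.

**Enrichment resampling.** Each draw samples, uniformly without
replacement from all network proteins: a shared block of size |P₁∩P₂|,
then the disjoint remainders of S₁ and S₂. The P-value uses the strict
inequality n′ > n, so ties favour enrichment. 1000 draws and the
α = 0.01 admission threshold are the defaults.

**Exact path search.** The optimiser is a best-first search over
simple-path states keyed by (cost, length, lexicographic node sequence).
Node entry costs DES(v) + λ are non-negative, so the key is monotone
along extensions and source→target states pop in globally sorted order;
the k-best ranked list is simply the first k popped solutions. This is
exact for the loopless problem — a hop-layered Dijkstra over (node,
hops) states is exact only up to walk/path equivalence and would need a
separate loopless k-best pass — and the 7-protein cap keeps the state
space small on bridge-sized graphs. Tie-breaking is deterministic:
shorter length first, then lexicographic node order.

**Cost forms.** The canonical objective sums node costs once. The
alternative edge-sum reading (each edge costs DES(u) + DES(v), which
double-counts interior nodes) is available as `--cost-form edge-sum` for
comparability; the two are related by the identity
edge-sum = node-sum + Σ interior DES, tested symbolically.

**Orphan attachment.** An orphan gene (no recorded interaction) is
linked to the up-to `max_partners` (default 10) bridge proteins with the
highest |Pearson r| ≥ `r_threshold` (default 0.6). With several
datasets, r is the mean over datasets measuring both genes — the same
averaging convention as the DES. Pseudo-edges carry no extra cost but
are flagged in every output so users can discount them. Attachment
refuses genes that already have real edges, and refuses to attach below
threshold rather than silently returning an unreachable orphan.

**TF scan.** Each candidate TF is pinned as the penultimate node: the
search runs ligand→TF on the graph minus the signature (total length
≤ 7 after appending the signature hop, which may be a pseudo-edge). TFs
absent, non-adjacent to the signature, or unreachable are reported
infeasible rather than erroring. Frequency summaries pool the per-TF
best paths (widen with `--paths-per-tf`), truncate to the `top_k`
lowest-cost paths, and count penultimate-slot and anywhere occurrences
separately.

## Synthetic scenarios

The generator emulates the study design the pipeline expects, with a
planted truth:

- **Network.** A 5-protein corridor PATH1–PATH5 chained edge to edge,
  each edge reinforced into a triangle by a dedicated TRI node (so every
  corridor protein lies on a loop motif); `n_planted_loops`
  vertex-disjoint triangles/squares each spanning P₁ and P₂ (these stay
  separate clusters, making the observed bridging count large); and
  Erdős–Rényi background edges drawn from all remaining pairs except
  those internal to the corridor block or to one loop (which would
  create corridor shortcuts or chords the construction must exclude).
- **Pathways.** P₁ holds the ligand end of the corridor plus one side
  of every planted loop; P₂ the TF end plus the other side; each padded
  with background genes.
- **Expression.** Background genes are i.i.d. Normal(0, σ²) in both
  conditions; corridor genes get a +5σ case shift with 10 + 10 samples
  (so their t-tests yield p ~ 10⁻⁹ while background p ~ Uniform(0,1));
  the signature is PATH5 plus Normal(0, (0.05σ)²) noise, giving
  Pearson r ≈ 0.999 with its regulator.
- **Presets.** tiny (6 loops, 20 background nodes, 1 dataset), small
  (8/40, 2 datasets), medium (10/80, 2 datasets). The planted path is 6
  proteins — inside the [2,7] bound and matching the span of a
  ligand→receptor→mediators→TF→signature cascade.

**Scenario attachment config.** Scenario pipelines attach the orphan
with `max_partners = 1`. This is a property of the generative model, not
a generic default: because every corridor gene shares the same
case/control mean shift, their pooled-sample correlations with the
signature are all ≈ Δ²/4 / (Δ²/4 + σ²) ≈ 0.86 at 5σ — above the 0.6
threshold — and a multi-partner attachment would create shortcut
pseudo-edges that bypass the corridor through genes whose correlation is
an artifact of shared differential expression rather than regulation.
Attaching only the strongest partner (r ≈ 0.999 vs ≈ 0.86, a wide
margin) encodes the single-regulator structure of the simulated truth.
Library defaults are unchanged.

**What the generator does not emulate:** microarray platform artifacts
(probe effects, normalisation, batch), scale-free degree distributions,
correlated background genes, and symbol-mapping noise between network
and expression identifiers. Passing the recovery test therefore shows
the machinery is correct under clean planted conditions, not that real
datasets will yield unambiguous paths.

## Numerical conventions and degenerate inputs

- t-test: equal-variance (classic Student), two-sided. Zero pooled
  variance resolves to p = 1 (equal means) or p = 0 (unequal means).
  Groups need ≥ 2 values.
- Unmeasured genes get DES = 1.0 (maximal cost), biasing paths toward
  proteins with expression evidence.
- Pearson correlation requires n ≥ 3 and non-constant vectors (constant
  input is an error, not r = 0).
- Fold change is log2(case/control), positive inputs only.
- Path costs are recomputable from (nodes, DES table, λ) to 1e-12;
  equality assertions in tests use exact dyadic cost grids where
  tie-order matters.
- Empty bridges (no pair passes enrichment) are warnings at build time
  and errors at search time.

## Verification problem sizes

The shipped verification suite uses: 50 random graphs ≤ 30 nodes for the
census/brute-force equivalence, 50 graphs ≤ 12 nodes for the path
optimiser/exhaustive-enumeration equivalence, 100 graphs for
degree-sequence preservation, an 8-protein universe (exhaustively
enumerable) with 3000 draws for enrichment calibration, 10,000 null
genes for the t-test type-I rate, and 50 tiny-preset scenarios for
planted-path recovery. These sizes make the full check reproducible on a
single CPU in minutes while keeping every comparison against a genuinely
independent oracle.

## Known limitations

- Exact-symbol matching between network, gene sets, and expression rows;
  no alias/identifier mapping.
- The undirected network cannot distinguish activation from inhibition;
  biologically impossible directions are not filtered (the correlation
  sign is reported to aid manual review).
- The best-first search is exponential in the worst case; it is intended
  for bridge-sized graphs (the hard 7-protein cap bounds the explored
  depth, and bridges are small by construction).
- Enrichment P-values are purely resampling-based; no analytic
  approximation is provided, so resolution is limited to 1/n_samples.
- Motif census supports k ≤ 4 and undirected graphs only.
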