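# Methods

## Graph model

A connectome is a simple directed graph over neurons. Loading binarizes
synaptic weights: an arc exists iff at least one connection with positive
synapse count links the ordered pair. Parallel connections collapse to one
arc, self-loops are removed, and both events are tallied in a `LoadReport`.
Binarization reflects the choice to compare connectomes whose exports do
not all carry comparable weight semantics; nothing downstream uses weights.
Node ids are opaque strings. Referential integrity is strict by default;
lenient loading creates group-null, side-unknown placeholder records for
dangling arc endpoints because real exports commonly contain them.

## Centrality conventions

Directed graphs that are not strongly connected leave several textbook
definitions underdetermined. The conventions below are defaults, not
facts; each is a `CentralityConventions` flag and is echoed into the run
manifest so any published number can be traced to the convention that
produced it.

* **Degree** is total degree (in + out). This one is not free: the
  published summary arithmetic (average degree = 2m/n) forces it.
* **Closeness** uses outward BFS distances with the Wasserman–Faust
  reachable-set correction, c(v) = (r−1)² / ((n−1) · Σ d(v,·)) over the
  r−1 nodes v reaches, and 0 when it reaches none. Inward distances are a
  flag (`closeness_direction="in"`). Distances come from
  `scipy.sparse.csgraph` BFS.
* **Betweenness** is exact directed Brandes over all ordered pairs,
  endpoints excluded, **unnormalized**; normalization by (n−1)(n−2) is
  applied only in the cross-connectome comparison. The igraph C
  implementation is used when importable, networkx otherwise; both are
  tested against brute-force shortest-path enumeration on small random
  digraphs.
* **Eigenvector centrality** follows the in-edge convention (a node is
  central when central nodes point to it; `eigenvector_direction="out"`
  flips it) and is computed independently on each weakly connected
  component, each component's vector scaled to unit maximum. Power
  iteration runs on Aᵀ + I: the identity shift leaves eigenvectors
  unchanged but guarantees geometric convergence on periodic components
  (a pure directed cycle has its spectrum on a circle and plain power
  iteration never settles). Tolerance 10⁻¹⁰ on the max-normalized change,
  1,000 iterations; non-convergence raises an error naming the component.
  Acyclic components have nilpotent adjacency (spectral radius 0, no
  Perron vector) and receive all-zero centrality — the one place where a
  "component with arcs has nonzero eigenvector values" expectation must
  fail, because no genuine eigenvector exists there. Components whose
  condensation chains several cycles of equal spectral radius converge
  only polynomially and will hit the iteration cap; such graphs are
  degenerate for this centrality and the error is intentional.
* **Path metrics** (average shortest path length, diameter) are computed
  over directed distances within the largest strongly connected component
  — the only scope in which all directed distances are finite — with an
  undirected-projection option. **Clustering** is the mean undirected
  local clustering coefficient.
* Isolated nodes score 0 on every centrality and therefore never enter
  top-quantile sets.

## Power-neuron detection

Top sets take exactly k = ⌊q·n⌋ ids per centrality (q default 0.20),
ranking by value descending with ties broken by ascending id so detection
is deterministic and purely rank-based (any strictly monotone per-
centrality transform leaves the result unchanged). k = ⌊q·n⌋ rather than
⌈q·n⌉ is inferred from the published set sizes (590 = ⌊0.2 · 2,952⌋;
162/590 = 27.46%); an `include_boundary_ties` option admits every id tied
with the boundary value, in which case sets may exceed k and overlap
percentages use the smaller set's size as denominator. The power set is
the exact four-way intersection; overlap percentages are |A∩B|/k · 100.

## Synthetic generator

The generator emulates the features of real insect connectomes that this
analysis is sensitive to, with exact ground truth:

* **Two mirrored hemispheres.** The left hemisphere is sampled, then
  copied onto the right through the homolog map, so homolog pairs are
  ground truth by construction. `mirror_noise` (default 0.05) rewires that
  fraction of right-hemisphere arcs to decay the symmetry; homolog
  partners share their `cell_type` attribute so attribute-based pairing is
  exercisable. Cross-hemisphere arcs appear with probability
  `cross_hemisphere_prob` (default 0.01), damped ×0.2 between unlike
  groups.
* **Group-block wiring.** Seven larva-like groups (sensory … brain
  outputs) with a feedforward-flavored block matrix (within-group 0.05,
  one-step-forward 0.02, background 0.008).
* **Heavy-tailed degrees.** Per-node in- and out-propensities drawn
  log-normal(μ=0, σ=1), median-rescaled to 1 so block probabilities keep
  their meaning for the typical pair. Arc probability is
  min(1, block · out-propensity · in-propensity · hub boosts); the clip at
  1 slightly biases the extreme upper tail. σ = 1 makes the
  99th-percentile/median total-degree ratio exceed 5 at n ≥ 500, the
  regime the heavy-tail observations describe.
* **Planted backbone.** A `hub_fraction` (0.05) of mirrored node pairs get
  a ×`hub_boost` (6) propensity multiplier plus direct hub–hub wiring with
  probability `hub_hub_prob` (0.3). Defaults give mean planted-hub recall
  ≈ 0.74 by power-neuron detection at n_per_hemisphere = 500 — the
  parameter-recovery surface the tests assert (≥ 0.70).
* **Unlabeled neurons.** `unlabeled_fraction` (0.1) of pairs get null
  groups (mirrored, so homolog semantics survive), exercising every
  "unclassified neurons are excluded from group statements" path.
* `plant_motifs` forces chosen cores to carry an exact motif signature by
  pruning out-of-signature labeled neighbors and adding one arc per
  missing group, for census round-trip tests.

What the generator does **not** emulate: spatial geometry, synapse
weights, realistic group-specific degree profiles, correlated
reciprocity, or any fit to real *Drosophila* statistics. Passing tests
therefore demonstrate correctness of the algorithms and the recovery of
planted structure under these statistical conditions, not fidelity of any
particular biological claim.

## Motifs and the QAP test

A core's motif is (core group, set of in-neighbor groups, set of
out-neighbor groups); unlabeled neighbors contribute no group and are
tallied separately. Census counts are numbers of distinct cores per
signature; per-group mean connection counts average distinct-neighbor
counts over occurrences. The QAP test shuffles group labels uniformly over
all nodes (a flag restricts the shuffle to labeled nodes, since the two
nulls differ when many neurons are unlabeled), holding the graph — and
hence the structure-derived core set — fixed, and recomputes the census
per permutation via integer-coded labels over precomputed neighbor index
arrays (O(arcs) per permutation, so N = 1,000 on a few-thousand-node graph
is interactive). The p-value is the strict-exceedance fraction
Σ ι(γⱼ > γ_obs)/N, exactly as defined, with no +1 correction; p = 0 is
attainable.

**Calibration caveat.** A key is only tested because it was observed, and
for keys with tiny occurrence probability this selection makes the raw
p-value anti-conservative: a signature seen once (γ_obs = 1) whose null
counts are almost surely 0 gets p ≈ 0 regardless of any real label
structure. The frequency threshold (`filter_frequent`, count ≥ 4 by
default, chosen via `sensitivity_scan`) is the guard: it removes exactly
the singleton keys the selection effect inflates. Calibration is
therefore asserted for the selection rule as used — p < 0.05 *and*
count ≥ 4 — on label-exchangeable fixtures
(`exchangeable_null_connectome`: three equal groups, uniform block
probability 0.10, σ = 0.3, no hubs, labels overwritten uniformly at
random, cores = top-20% degree). Measured false-positive rates over
20-seed blocks are 0.02–0.10 (mean ≈ 0.05) at N = 200 permutations.

## Distribution comparison

Degree is normalized by its maximum possible value 2(n−1) in a simple
digraph, betweenness by the directed ordered-pair count (n−1)(n−2);
closeness and eigenvector are already bounded by their conventions. All
values then pass through log₁₀(1+x), which preserves ranks, so KS D and
Mann–Whitney U are unchanged by it (asserted as a property). Mann–Whitney
uses exact enumeration for tie-free samples up to 50 per side and the
tie-corrected normal approximation otherwise; Cliff's δ = 2U/(n_a n_b) − 1
with U counting (a > b) pairs plus half-ties; BH adjustment
(statsmodels step-up) is applied jointly across the four centralities.
The subsampling control redraws equal-size subsamples from the larger
network, keeping each node's full-network centrality (degrees are not
recomputed on the induced subgraph; a flagged alternative reading would
recompute them — not implemented because the subsample is a sampling
control, not a new network). Pooled-percentile cutoffs use linear
interpolation; exceedance is strict.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by design:
n_per_hemisphere = 500 (graphs of 1,000 nodes) for recovery surfaces, 150
for QAP calibration (N = 200 permutations, 20 seeds), ≤ 15 nodes for
brute-force oracles. The pipeline derives per-stage seeds from one master
seed by fixed offsets; reruns with the same configuration are identical,
and the manifest records every flag, seed, and load count. Full-scale
adult-connectome analysis (10⁵ nodes) is supported in principle by the
same code paths but exact betweenness at that size is the binding cost and
is out of scope here.

## Known limitations

* Eigenvector centrality on components with tied dominant eigenvalues
  across condensation blocks does not converge (see above); this is
  reported, not silently resolved.
* The published larval power-neuron count (162) is sensitive to closeness
  direction, eigenvector convention, and quantile tie handling; without
  the deposited data the matching combination cannot be established, which
  is why every convention is a recorded flag rather than a constant.
* Greedy ascending-id pairing of ambiguous homolog classes (several
  candidates on both sides) is a convention; the ambiguity list preserves
  auditability.
* The generator's hemispheric mirror is exact at mirror_noise = 0, which
  real bilateral symmetry is not; homolog-recovery results at 0 noise are
  upper bounds.
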