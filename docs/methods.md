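# Methods

## Model

A multiplex network is a shared ordered node list with `N ≥ 2` undirected,
simple, binary edge layers.  The utility under study is pairwise efficiency
`f(ω; E) = 1 / l(ω; E)` — the inverse shortest-path length of node pair
`ω`, zero for disconnected pairs — and its expectation
`F(E) = E[f(Ω; E)]` under a probability weighting `p(ω)` over unordered
distinct pairs.  With the default uniform weighting `F` is global
efficiency.  Pairs are unordered because the graphs are undirected; the
diagonal never enters expectations.

The central objects are the efficiency atoms of each pair.  For two layers:

* redundancy `r = min(f_A, f_B)` — the efficiency the *worse* layer still
  provides, i.e. what an agent could achieve knowing either layer alone;
* unique `u_j = f_j − r` — the better layer's surplus (at least one of the
  two is always zero);
* synergy `s = f_joint − max(f_A, f_B)` — the surplus that only the union
  provides, i.e. shortest paths that mix edges from both layers.

These are non-negative (unions can only shorten paths) and sum exactly to
`f_joint`, so their expectations give
`F(joint) = R + U_A + U_B + S`.

For general `N`, atoms live on the lattice of antichains of nonempty layer
subsets.  The redundancy function is
`F∩(α) = E[min_{a∈α} f(Ω; E_a)]`, where `E_a` is the union of the layers
in subset `a`.  It satisfies symmetry, self-intersection
(`F∩({a}) = F(E_a)`), deterministic equality (an argument whose edge set
contains another argument's can be dropped) and monotonicity (adding an
argument never increases it); `verify_axioms` checks all four numerically
on any given multiplex.  Atoms are the Möbius inversion of `F∩` over the
partial order `α ≼ β ⇔ ∀b∈β ∃a∈α: a ⊆ b`.  Because the source material
for this order points to the partial-information-decomposition literature
without restating it, we adopt the standard redundancy-lattice (Williams–
Beer) convention and verify it self-consistently: the reconstruction
`F∩(α) = Σ_{β≼α} F∂(β)` holds at every node, all atoms are non-negative,
and for `N = 2` the four atoms coincide with the closed-form `R, U_1, U_2,
S` above on every tested instance.

A pair's *dominant character* is the ≼-highest antichain with a strictly
positive per-pair atom.  For `N = 2` it is unique and equals the
length-based classification (synergistic / unique / redundant).  For
`N > 2` uniqueness is not proven; when several antichains qualify the
implementation reports all of them rather than resolving the ambiguity.

Pairs disconnected even in the joint network are labelled *unreachable*:
their atoms are all zero (so conservation is unaffected), they are kept in
the per-pair table, and they are excluded from class-proportion
denominators by default (`include_unreachable=True` gives the sensitivity
variant).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `swaps_per_edge` | 10 | attempted double-edge swaps per edge in degree-preserving rewiring; common practice for full randomization |
| `n_bins` | 10 | edge-length histogram resolution of the geometry-preserving null; swaps must preserve the per-bin counts exactly |
| `n_surrogates` | 1000 | null-ensemble size; gives an empirical-p floor of 1/1001 |
| SWP `n_random` | 10 | ER reference realizations averaged per SWP evaluation; the lattice reference is deterministic and cached |
| sweep `n` | 50 | node count of the Erdős–Rényi density sweep (see below) |
| rewiring experiment | n=200, density 5%, step 1% | ring lattice with k=5 neighbours per side (1000 edges, the count closest to 5% density); each step performs `step·m/2` double-edge swaps, i.e. nominally displaces a further 1% of edges |

Node labels are opaque strings; all matrices are indexed by the multiplex
node order.  Padding (nodes missing from a layer become isolated there) and
dropping (nodes isolated in every layer are removed) happen exactly once,
at `build_multiplex`.

## Synthetic data: what it emulates and what it does not

The generators produce the study systems on which the method's published
behaviour is established:

* **ER layer pairs** (`er_pair`, `density_sweep`): independent `G(n, m)`
  layers with `m = round(f·n(n−1)/2)` — fixed edge count, not
  independent-probability, so density is exact.
* **Lattice rewiring** (`rewiring_experiment`): two copies of a ring
  lattice; one evolves by cumulative degree-preserving swaps, 1% of edges
  per step.  Cumulative evolution matches a progressive-randomization
  protocol; a fresh-copy-per-step variant exists behind
  `cumulative=False`.
* **Spatial networks** (test fixtures): uniform random coordinates in a
  cube with ER edges, for the distance split and the geometry-preserving
  null.

These share none of the heavy-tailed degree, modular or geometric structure
of real transport networks or connectomes; passing tests on them
demonstrates the correctness and calibration of the machinery, not that any
empirical system is synergy- or redundancy-dominated.  Real data (e.g. a
public multiplex edge list) can be fed through the same entry points.

**Choice of `n = 50` for the density sweep.**  The regime map of ER layer
pairs — synergy dominant where both layers are ~5% dense or sparser,
redundancy dominant on the equal-density diagonal above ~15%, the denser
layer's unique class dominant under strong imbalance — is a function of
mean degree, not density alone, so the boundaries move as `n` changes.  At
`n = 50` all three regimes sit at the densities quoted above; at `n = 200`
the synergy-dominant corner has already shrunk below 2% density (a 5%-dense
200-node graph has mean degree ≈ 10 and is locally far from tree-like).
The sweep takes `n` as an argument; 50 is the default because it is the
size at which the quoted regime boundaries are the observed ones.

## Numerical choices

* Conservation and reconstruction identities hold to `1e-12` and are
  asserted at that tolerance; atom non-negativity allows `−1e-12` slack.
* Antichain enumeration is capped at `N = 4` (counts grow as the Dedekind
  numbers: 4, 18, 166); larger `N` requires an explicit override.
* Shortest paths: BFS (binary) or Dijkstra (weighted) via
  `scipy.sparse.csgraph`.  Weighted support (length = sum of weights,
  efficiency = 1/length, no normalization) is experimental; every numeric
  experiment here is binary.
* Rewiring: a double-edge swap proposal is rejected if it would create a
  self-loop or duplicate edge (and, in the geometry-preserving model, if
  the two new edges do not occupy the same multiset of length bins as the
  two removed ones — preserving the binned histogram exactly).  The
  attempt budget is 100× the target swap count; degenerate graphs that
  exhaust it (e.g. stars) are returned unchanged with a warning.
  `n_bins=1` makes the geometric model coincide with plain rewiring.
* Seeds: ensembles and experiments spawn per-surrogate, per-layer child
  seeds from the master seed via `numpy.random.SeedSequence`, so results
  are bit-reproducible and parallelizable.  The rewiring experiment gives
  the trajectory and the SWP references independent child streams, so the
  trajectory does not depend on whether SWP is evaluated.
* SWP: `ΔC` and `ΔL` are clamped to `[0, 1]` before combining — required
  for the stated `[0, 1]` bound when the observed statistics fall outside
  the reference envelope.  Degenerate reference denominators set the
  corresponding deviation to 0 and flag the result.  Disconnected inputs
  are summarized over reachable pairs (the component-weighted mean path
  length) rather than the largest component only; the two agree on
  connected graphs and the result carries a `disconnected` flag either
  way.
* Distance split: edges sort by `(Euclidean length, canonical edge id)`;
  the extra edge of an odd count goes to the short-range layer.  Density
  matching ranks by absolute weight by default (signed option available)
  and breaks cutoff ties by canonical index order.  Consensus keeps a pair
  only when *strictly more than half* of subjects have it.
* Statistics: empirical p-values carry the add-one correction
  (`p ≥ 1/(n_null+1)`); the paired permutation test sign-flips differences
  with a paired-t statistic, enumerating all `2^n` patterns exactly for
  `n ≤ 10`.  No multiple-testing correction is applied by default
  (a Bonferroni option exists).

## Known limitations

* The method counts a pair once regardless of how many equally short paths
  realize its shortest length within a layer; within-layer path
  multiplicity is outside the model.
* Switching between layers is free; cost-aware variants would reduce
  synergy and are not implemented.
* Directed graphs and multigraphs are not supported.
* The dominant-character ambiguity for `N > 2` is surfaced, not resolved.
* In the rewiring experiment the rewired layer's unique-contribution curve
  has a broad, flat maximum (its argmax over replicate runs spans several
  percentage points) while the joint network's SWP peak is sharp; in this
  implementation the SWP peak tends to sit two-to-three steps *before* the
  unique-contribution peak rather than exactly on it, so coincidence of
  the two peaks should be read as approximate.
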