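# Methods

## The modelling problem

A neural connectome at the cellular scale is an undirected graph whose
nodes are neurons and whose edges mark the presence of at least one
chemical synapse; edge weights, when used, are synapse counts. Each
neuron also has a position — the mean of its surface-mesh vertices
("center of mesh") — and, at finer resolution, a surface point cloud.
The contactome links neurons whose surfaces approach within tens of
nanometres; since synapses require contact, the connectome is a
subnetwork of the contactome and the two form a two-layer (multiplex)
network on one node set.

`neuromaxent` fits canonical maximum-entropy ensembles to such data:
distributions P(G) over graphs that maximise entropy subject to
constraints that hold on average (soft) or absolutely (hard). All six
kinds factorise over node pairs, so each is fully described by
independent edge probabilities p_ij and can be sampled directly without
Markov-chain Monte Carlo:

| kind  | constraints                                   | p_ij |
|-------|-----------------------------------------------|------|
| d     | binned connection probability p(d)            | p_b(d_ij) |
| k     | expected degrees k_i*                         | 1/(1 + x_i x_j) |
| k+L   | expected degrees and total wiring length L*   | 1/(1 + x_i x_j e^{d_ij/d0}) |
| c     | expected edge count, contact mask             | E*/E_cont on contact pairs |
| d+c   | conditional p(d), contact mask                | p_b(d_ij) on contact pairs |
| k+c   | expected degrees, contact mask                | 1/(1 + x_i x_j) on contact pairs |

x_i = e^{θ_i} are exponentiated Lagrange multipliers. The wiring length
L = Σ_edges d_ij uses Euclidean distance between node positions,
reported throughout in soma-size units (μm divided by the organism's
typical soma radius), which puts the decay scales of different
organisms on a common footing.

## Fitting

**Degree models (k, k+c).** The multipliers solve
k_i* = Σ_{j≠i, allowed} 1/(1 + x_i x_j). We iterate the standard
fixed-point update x_i ← (1/k_i*) Σ_j 1/(1/x_i + x_j), initialising
x_i = √(Σ_j k_j*)/k_i* (the sparse-limit solution), mixing 0.5 with the
previous iterate whenever the residual grows, and stopping when the
maximum relative degree error max_i |⟨k_i⟩ − k_i*|/max(k_i*, 1) drops
below 1e-8 (cap 10,000 iterations). With a contact mask the sums run
over allowed pairs only and p_ij = 0 elsewhere.

**Boundary peeling.** The interior fixed point exists only when the
target sequence lies strictly inside the polytope of expected degree
sequences. Two deterministic cases are resolved exactly before
iterating: a node with k_i* = 0 gets p_ij = 0, and a node whose target
equals its allowed partner count forces p_ij = 1 on all its pairs.
Forcing consumes one degree unit from each partner, which can create
new saturated or exhausted nodes, so the reduction is applied
iteratively until only an interior problem remains; the forced pairs
are stored explicitly and the affected nodes are reported as boundary
nodes. Targets that exceed the partner count at any stage raise an
infeasibility error. *Known limitation:* sequences saturating a
multi-node facet of the polytope (an Erdős–Gallai prefix inequality
holding with equality, without any single node being saturated) still
lack an interior solution; there the iteration approaches the boundary
only algebraically and ends in a convergence error carrying the
residual. Realized degree sequences of connectome-scale data do not hit
this in practice; it matters only for tiny dense graphs.

**Degree + wiring length (k+L).** For a trial decay scale d0 the same
fixed point is solved with pair weights e^{d_ij/d0} (warm-started
between trials); the expected length ⟨L⟩(d0) = Σ p_ij d_ij is monotone
increasing in d0, so d0 is found by geometric bisection on a bracket
(default [d̄/20, 50 d̄] around the mean pair distance d̄) until
|⟨L⟩ − L*|/L* ≤ 1e-4, i.e. one hundredth of one percent of the total
edge length. Bracket ends within tolerance of L* are accepted directly,
which also covers the degenerate all-distances-equal geometry where
⟨L⟩ no longer depends on d0. Exponents are clipped at 700 and x at
1e±150; outside those ranges p_ij under/overflows to exactly 0 or 1
anyway.

**Distance models (d, d+c).** Pair distances are split into 50 linear
bins spanning [0, max distance] (half-open, last bin closed) and each
bin's probability is its connected fraction, p_b = edges_b / pairs_b.
With a contact mask both numerator and denominator are restricted to
contact pairs and the probability applies to contact pairs only — the
conditional connection curve. Either way Σ_pairs p = E exactly, by
construction. A pair scored beyond the last bin edge (possible when
scoring pairs not used in fitting) receives the last bin's probability
with a warning.

**Sampling and likelihood.** Realization r of an ensemble uses a fresh
generator seeded seed + r and draws every allowed pair independently.
The Bernoulli log-likelihood of an observed graph is
Σ_edges ln p_ij + Σ_non-edges ln(1 − p_ij); an observed edge with
p_ij = 0 (e.g. outside the contact mask) yields −inf with the offending
pairs listed.

## Spatial statistics

The decay scale d0 of p(d) ≈ α e^{−d/d0} is estimated by least squares
on ln p_b against bin centers, weighted by per-bin edge counts, using
only bins with at least 10 edges (the rule also used for display) and
below the finite-size cutoff d_fs. d_fs is the mode of the all-pairs
distance histogram (same 50-bin default; ties resolve to the smaller
distance): beyond it the bounded experimental volume depletes pairs and
distorts p(d). Soma radii are estimated as the peak of a
triangular-kernel density (grid step = bandwidth/10, ties to the
smaller mode) of center-to-contact distances; bandwidths of order
0.2–1.5 μm are appropriate for fly- to human-sized somata. Directional
decay scales are fitted per principal axis of the position cloud
against |Δposition·axis|, over the full projected range (the 3D
finite-size cutoff has no direct analogue for 1D projections, whose
pair-offset density peaks at zero).

## Contactome construction

For each pair of point clouds the exact minimum inter-point distance
d_min is found by KD-tree nearest-neighbour queries (optionally pruned
by a center-distance cutoff). The contact threshold is the smallest
integer number of nanometres t such that the fraction of synaptic pairs
with d_min strictly below t reaches the target coverage (default 99%).
Contact edges are the pairs below threshold, plus any uncovered
synaptic edges (the "top-up"), so the subset invariant holds exactly.

## Synthetic scenarios

The generator plants a full multilayer data set with known truth, used
by the test suite in place of the multi-terabyte volumetric data:

- **Positions:** n nodes uniform in a box, default 100-unit cube
  (distances read as soma sizes), optionally anisotropic.
- **Contactome:** each pair linked with probability
  min(1, s·e^{−d/d0_c}), default d0_c = 12 soma sizes and s = 1 —
  matching the order of the decay scales measured in real contactomes.
- **Connectome:** each contact edge kept with probability
  1/(1 + x_i x_j), x log-normal with σ = 1 (broad but not scale-free
  degrees), rescaled by a 1-D root solve so the expected kept fraction
  is 0.25 (the connectome-to-contactome edge ratio observed in the
  fly); σ = 0 reduces to a uniform random subnetwork.
- **Weights:** w = 1 + ⌊LogNormal(ln(20 p), 1)⌋ per edge — heavy-tailed
  positive integers whose mean rises with the planted edge probability.
- **Point clouds:** 300 points per node, 80% on a soma sphere (radius
  2.5 μm) and 20% at uniform radii out to 15 μm (neurite reach). Cloud
  scenarios use 60 nodes in a 40 μm box; the true contact set is the
  bottom 0.15 quantile of pairwise d_min, and half of it is synaptic.

What the generator does **not** emulate: realistic neurite
morphologies, cortical layering, neuron types and wiring specificity,
reconstruction artefacts (split/merged segments, cropped neurons), or
distance-dependent synapse multiplicity. Passing tests therefore
establish correctness of the estimators and solvers under the stated
generative assumptions, not biological fidelity of any particular fit.

## Evaluation conventions

- Graphlets (triangle, 4-cycle "square", diamond, K4) are counted as
  induced subgraphs, from per-edge common-neighbour counts with overlap
  corrections (each K4 contains 6 non-induced diamonds and 3 non-induced
  4-cycles; each diamond 1 non-induced 4-cycle); the counter is checked
  against exhaustive enumeration in the tests.
- Diameter and average geodesic distance are computed on the largest
  connected component (they are infinite otherwise); global efficiency
  averages 1/δ over all ordered pairs with 1/δ = 0 when disconnected;
  local efficiency averages the global efficiency of neighbour-induced
  subgraphs; clustering of nodes with fewer than two neighbours is 0.
- Degree summaries (mean, median, their ratio, IQR) are over all nodes,
  isolated ones included; quartiles use linear interpolation.
- The wiring-length optimality test permutes the position-to-node
  assignment uniformly, keeping topology fixed, and reports the mean
  shuffled-to-observed ratio and the one-sided permutation p-value with
  +1 smoothing, p = (#{L_perm ≤ L_obs} + 1)/(n_perm + 1).
- Edge classification uses tie-grouped ROC with trapezoidal AUC and
  step-interpolated average precision (appropriate under the extreme
  sparsity of synaptic edges among candidate pairs); probability-weight
  association uses Spearman rank correlation with average ranks.
- Ensemble comparison reports z = (data − mean)/sd over realizations
  (default 100), the two-sided normal p, significance stars at
  0.05/0.01/0.001, and the inverse fold change mean/data.

## Problem sizes and numerical defaults

The test suite and the acceptance script run on scenarios of 60–2000
nodes (500 for the wiring-length calibration and parameter-recovery
checks; 2000 where binned-curve recovery needs statistics), sizes at
which every estimator's sampling error is comfortably inside the
asserted tolerances. Key defaults: degree tolerance 1e-8, wiring
tolerance 1e-4 (relative), 50 distance bins, 10 edges minimum per
fitted bin, 99% contact coverage, 100 ensemble realizations,
realization r seeded seed + r.
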