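# Methods

## Problem setting

Input: an undirected simple graph `G = (V, E)` over string vertex ids that
splits into `p` connected components `V_1 … V_p`, and a symmetric, zero-
diagonal, nonnegative dissimilarity matrix `D = (d_ij)` over all vertex
pairs. The matrix typically comes from a different data source than the
edges (e.g. edges from thresholded functional similarity, distances from an
integrated gene-similarity score), so it carries information *between*
components that the graph itself does not. The goal is a 2-D layout in which
Euclidean distance tracks `d_ij` both within and across components.

All matrices are label-addressed (pandas DataFrames indexed by vertex id);
nothing is ever matched positionally.

## Stage one: internal component layouts

Each component is laid out independently with the Fruchterman–Reingold
algorithm (`networkx.spring_layout`, ideal edge length `1/sqrt(n)` on unit
area, linear cooling, 500 iterations by default — components in the intended
use cases are small, so convergence is cheap) and then mean-centered. Every
component's layout seed is derived deterministically from the single
user-facing seed, so runs are reproducible bit for bit.

FR coordinates carry an arbitrary unit. Because stage two connects
components by springs whose rest lengths are in the units of `D`, each
component's internal layout is rescaled once so that its mean internal
pairwise layout distance equals its mean internal pairwise dissimilarity.
This makes the internal and global coordinate systems commensurate — the
rigid-body spring system is otherwise ill-posed, its equilibrium depending
on an arbitrary unit choice. Singletons and components whose internal
dissimilarities are all zero are left untouched. For a single-component
network the rescale is skipped entirely: there is no inter-component frame,
and the pipeline then reduces *exactly* (bit for bit) to whole-graph FR.

## Stage two, exact: rigid-body spring simulation

Every cross-component vertex pair `(i, j)` is joined by a Hooke spring with
rest length `d_ij` and unit stiffness:

    F_ij = (d_ij − ‖g_i − g_j‖) (g_i − g_j) / ‖g_i − g_j‖

where `g_i = R(φ_k) v_i + c_k` is the global position of vertex `i` of
component `k` with centered local coordinates `v_i`, rotation `φ_k` and
center `c_k`. Springs *within* a component are omitted: in a rigid body the
internal pair forces cancel in both the force sum and the torque, so
including them changes nothing (this is asserted numerically as an
invariant test rather than assumed).

Assuming infinite friction (no momentum), one step of component `k` is

    Δc_k = η_c · ( Σ_i F_i ) / |V_k|
    Δφ_k = η_φ · ( Σ_i r_i × F_i ) / ( Σ_i ‖v_i‖² )

with `r_i = R(φ_k) v_i` the *current rotated* arm (torque must be evaluated
in the current orientation) and `×` the scalar 2-D cross product; the
denominator is the moment of inertia per unit mass, so the vertex mass
cancels throughout. Singletons have zero inertia and never rotate.

Numerical choices:

* The step constants default to `η_c = η_φ = 0.1` and are interpreted **per
  spring**: each is divided by the number of cross-component partner
  vertices. The mean force on a vertex grows linearly with the number of
  springs attached to it, so a fixed step diverges beyond a few dozen
  vertices while a per-spring step keeps the stable region independent of
  problem size. With small steps the total stress decreases monotonically
  (property-tested).
* Convergence: stop when the largest per-vertex force norm drops below
  `1e-4` (in the units of `D`), or after 2000 iterations. A per-iteration
  log `(iteration, max_force, total_stress)` is kept and can be written as
  TSV.
* Coincident global positions get a seeded random repulsion direction with
  magnitude `d_ij` (and a warning); antisymmetry `F_ij = −F_ji` is preserved
  on this fallback.
* Initialization: seeded random centers uniform in a square scaled by the
  mean off-diagonal dissimilarity, random initial rotations. A non-finite
  state aborts with an error rather than silently clipping.

The objective implicitly minimized is the raw stress over inter-component
pairs, `Σ_{i<j} (d_ij − ‖g_i − g_j‖)²`; zero-force configurations are fixed
points, and translating all centers together changes nothing.

## Stage two, fast: component MDS plus annealed rotation

The simulation is accurate but slow (`O(|V|²)` force evaluations per step).
The approximation replaces vertex-level placement with component-level
placement:

1. **Component distances.** `δ_kl` is the average-linkage distance: the mean
   of `d_ij` over all cross pairs between `V_k` and `V_l`. (Cross-checked in
   the tests against the final merge height of hierarchical average-linkage
   clustering.)
2. **SMACOF MDS.** The `p` centers are embedded in the plane by minimizing
   raw stress `Σ_{k<l} (δ_kl − ‖c_k − c_l‖)²` with the Guttman majorization
   transform, which guarantees a monotonically non-increasing stress — this
   guarantee is asserted on every run of the test suite. Iteration stops
   when the relative stress decrease falls below `1e-9` (default) or after
   300 iterations. One point maps to the origin; two points are placed
   exactly at distance `δ_12`. Initialization is seeded-random in the unit
   disk by default, with an optional classical-scaling (Torgerson
   double-centering) start. SMACOF is implemented in-package because the
   per-iteration stress trace is part of the method's contract;
   scikit-learn's implementation serves as an independent cross-check in the
   tests, where both majorizers reach the same raw-stress optimum.
3. **Scale coupling.** `scaling_factor` returns `K = v̄ / ḡ`, the ratio of
   the mean component size (mean intra-component pairwise vertex distance,
   averaged over components with ≥ 2 vertices) to the mean pairwise center
   distance. Global positions then use `g_i = R(φ_k) v_i + K c_k`. The ratio
   exists to prevent component overlap when the two coordinate systems are
   incommensurate. Because stage 1.5 already expresses internal layouts in
   `D` units, shrinking the center spread below its MDS geometry would only
   discard inter-component structure, so the pipeline applies the ratio as
   an overlap guard: `K = max(1, v̄/ḡ)`. (Applying `v̄/ḡ` unconditionally
   forces mean spacing ≈ mean component size regardless of the data — a map
   barely two component-diameters wide — which measurably destroys the
   layout–distance correlation whenever components are non-trivial.) If all
   components are singletons `K := 1` with a warning and the procedure
   degrades gracefully to pure MDS of `D`, which it then matches bit for
   bit; coincident centers are an error.
4. **Rotation.** Centers stay fixed; each sweep visits components in
   ascending index and applies the same torque rule as the simulation
   (forces evaluated at the scaled positions, rest lengths unchanged). To
   escape local minima the step is *reversed* with probability
   `exp(−1/T_s)`, `T_s = t0 · decay^s` (defaults `t0 = 1`, `decay = 0.9`,
   50 sweeps). A reversed exploration move is always applied; a forward move
   is applied only if the global stress does not increase, so the
   zero-temperature limit is strictly greedy and monotone. Reflections are
   not searched — only rotations. Singletons keep `φ = 0`.

Degenerate limits (both exercised as acceptance tests): a connected network
bypasses stage two entirely and equals whole-graph FR bit for bit; an
edgeless network reduces to plain MDS of `D` bit for bit.

## Evaluation

`layout_correlation` reports the Pearson correlation between the
upper-triangle entries of `D` and the corresponding layout distances over
*all* vertex pairs (intra- and inter-component), plus the raw stress and the
pair count. The statistic is invariant under rigid motions and uniform
scaling of the layout; constant inputs are flagged as undefined rather than
propagating NaNs. `fragmentation_sweep` rebuilds the network at a rising
sequence of similarity thresholds (keeping isolated vertices so the vertex
set is fixed), runs each registered method with shared derived seeds, and
tabulates mean correlation, component count and average local clustering
coefficient per threshold. `nearest_component_links` lists, for each
component, its `k` most similar partners with weights
`(δ_max − δ_kl)/δ_max`, used as background-line widths in the SVG rendering.

The average local clustering coefficient follows the Watts–Strogatz
convention: vertices of degree < 2 (whose coefficient is undefined) are
excluded from the average, so complete graphs score exactly 1.

Thresholded network construction uses strict inequality (score >
threshold).

## Synthetic benchmarks

`planar_instance` plants Gaussian groups around jittered-grid centers and
returns the *exact* planar Euclidean distance matrix (so plain MDS can reach
zero stress — ideal for recovery tests) together with a network built by
thresholding the similarity `s = 1/(1+d)` at the midpoint between the
largest within-group and smallest between-group distance (20th-percentile
fallback when groups overlap). Defaults — 60 points, 12 groups, within-group
spread 0.4 versus grid spacing 3.0 — produce the regime the method targets:
many small components (typically a handful of vertices each, high local
clustering) whose arrangement is unconstrained by edges.

`block_dissimilarity` plants an ultrametric-like block structure
(`d_within` inside, `d_between` across, optional per-block-pair distances
and symmetric jitter) and thresholds midway, making each block exactly one
clique component. With jitter or with more than three mutually equidistant
blocks the matrix is *not* planar-realizable, emulating noisy real
similarity scores.

What these generators do **not** emulate: heavy-tailed degree distributions,
missing or censored dissimilarities, and matrices whose intrinsic
dimensionality is far above two (real gene-similarity matrices cap the
achievable correlation for every method at well below 1). A high correlation
on these benchmarks therefore demonstrates correctness of the optimization,
not expected field performance on any particular biological matrix.

## Determinism

Every stage draws from a child seed derived from the single user seed via
`numpy.random.SeedSequence` spawn keys (per-component FR, MDS init,
annealing, simulation init, coincidence guards). Identical seeds and inputs
give bit-identical coordinates; the acceptance script's numbers are fully
determined by its `--seed`.

## Known limitations

* The rotation stage optimizes one component at a time; strongly coupled
  rotations can stall in local minima (the annealing mitigates but does not
  eliminate this — occasionally the fast approximation beats the exact
  simulation, which starts from a random placement and can itself get
  stuck).
* No overlap removal is applied after placement; an overlap count (pairs of
  intersecting component bounding circles) is reported as a diagnostic only.
* Edge weights are ignored inside components (FR runs unweighted), and
  directed or multi-edge graphs are out of scope.
* The exact simulation's `O(|V|²)` cost per iteration makes it impractical
  beyond a few hundred vertices; that is precisely the niche of the
  approximation.
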