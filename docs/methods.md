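# Methods

## Model

`chaostopo` couples one 3-variable chaotic oscillator per data point
through a network extracted from pairwise structure, and reads off each
point's role from how its trajectory behaves across a family of coupling
topologies.

**Nodal dynamics.** Lorenz, `ẋ = α(y−x), ẏ = x(γ−z) − y, ż = xy − βz`,
with α=10, γ=60, β=8/3 by default (a strongly chaotic regime), or Rössler,
`ẋ = −y−z, ẏ = x+ay, ż = b+z(x−c)`, with a=b=0.1, c=4.  All parameters are
dimensionless.  A second Rössler-style set (a=35, b=3, c=28) circulating in
the literature coincides with the Chen system's parameters rather than a
chaotic Rössler regime; it is configurable but not a default.

**Coupling.** `dx_i/dt = F(x_i) + ε Σ_j G_ij Γ x_j` with `G` symmetric and
zero-row-sum, `ε ≥ 0`, and `Γ` a 3×3 linking matrix (identity by default:
all components couple).  Since `Σ_j G_ij = 0`, the coupling term is zero
whenever all states agree, so the synchronization manifold is invariant for
every `ε` and every admissible `G`.  The implementation subtracts node 0's
state before applying `G` — algebraically a no-op, but it makes the
cancellation exact in floating point, so ensembles started identically stay
identical to the last bit instead of being torn apart by chaotically
amplified round-off (~1e-8 after a few thousand steps otherwise).

**Interaction kernels.** From a distance matrix: hard-cutoff contact
(Kirchhoff), generalized exponential `exp(−d^κ/(κσ^κ))` (the default, with
κ=1, σ=3 — at κ=1 this is `e^{−d/σ}`), or power law `(d/σ)^{−ν}`, ν>1.
From signals: |Pearson correlation| between channels (signed correlations
available by flag; the absolute value keeps off-diagonals nonnegative so
the zero-row-sum convention applies unchanged).  The diagonal is always
the negative off-diagonal row sum, never a self-correlation.

**Laplacian filtration.** For a weighted zero-row-sum matrix with
off-diagonal weights `l_ij`, let `l_min`, `l_max` be the extreme
off-diagonal weights and `d = l_max − l_min` (the diagonal is excluded:
including it would make the thresholds vacuous).  Level k ∈ {1..p} keeps
the edges with `l_ij > (k/p)·d + l_min`, assigning weight −1 (positive
diagonal; a standard PSD graph Laplacian).  Edge sets are nested and
level p is always empty — the family sweeps from near-full connectivity to
isolated nodes.  The dynamics consume `G = −L^k`, so retained edges couple
attractively for ε>0.  A weighted variant keeps `−l_ij` instead of −1, and
a radius mode thresholds on distances (`d_ij ≤ 2α`) for geometric
demonstrations.  The default p=10 balances multiscale coverage against
integration cost.  The last threshold is pinned to `l_max` exactly so
round-off in `l_min + d` cannot leave a stray edge in the empty level.

**Simplicial persistent Laplacians.** Vietoris–Rips complexes include a
simplex when all pairwise vertex distances are ≤ 2α (α a ball radius;
a `≤ α` diameter dialect is available), capped at dimension 3, which is
all that persistent Laplacians of order q ∈ {0,1,2} need.  For a nested
pair `K_t ⊆ K_{t+p}`, the persistent boundary operator acts on the
subspace of (q+1)-chains of `K_{t+p}` whose boundary lies in `C_q(K_t)`;
its matrix `B_{q+1}^{t,p}` is computed on an orthonormal basis of that
subspace (null space of the boundary rows that leave `K_t`), and
`L_q^{t,p} = B_{q+1}^{t,p}(B_{q+1}^{t,p})ᵀ + (B_qᵗ)ᵀB_qᵗ`.  The kernel
dimension equals the persistent Betti number; this identity is verified in
the tests against an independent rank–nullity computation
(`dim ker ∂_qᵗ − dim(im ∂_{q+1}^{t+p} ∩ C_q(K_t))`, with the intersection
dimension obtained from the rank identity `rk U + rk W − rk [U W]`), which
shares only boundary-matrix assembly with the Laplacian route.  Zero
eigenvalues are detected at the scale-aware tolerance
`10⁻⁸ · max(1, λ_max)`.  Dense symmetric eigensolvers are used throughout;
all intended use-cases stay below a few thousand simplices.

## Integration

Fixed-step forward Euler, midpoint RK2 and classical RK4.  The toy
synchronization demonstrations use Euler with h=10⁻³ over 20,000 steps;
the feature pipelines use RK4.  Empirical global-error orders (1, 2, 4)
are verified against an RK4 reference at h=10⁻⁶ on a short chaotic
segment (t ≤ 0.2, before exponential divergence dominates).  A divergence
guard aborts with the offending step index when any state magnitude
exceeds 10⁶; diverging scales are reported, never silently imputed.  Note
the explicit-scheme stability limit: with strong coupling the fastest
network mode has rate ≈ ε·λ_max(L), and ε·λ_max·h must stay below the
scheme's stability bound (≈2.8 for RK4); the 300-sample classification
runs therefore use ε=4 rather than the flexibility pipeline's ε=13.6.

## Feature extraction

Per node, per state component, over the post-transient segment (last 75%
by default): mean, standard deviation, min, max, median, skewness and
excess kurtosis — 21 features per scale, concatenated over all p scales in
filtration order.  The set is configurable; moments of constant series are
defined as 0.  Two modes:

* **perturbative** (element-specific, used for flexibility): one run per
  target node, target started at state 1 in all three components, all
  other nodes at rest; only the target's own trajectory is summarized.
  Runs are batched — batch members are independent copies, so batching is
  exact — and only target trajectories are recorded, keeping memory at
  O(N·T).  The empty last scale yields identical rows across nodes
  (uncoupled targets all start identically), so perturbative designs are
  structurally rank-deficient there; downstream least squares falls back
  to the pseudoinverse with a warning.
* **shared_random_init** (sample-level, used for classification): one run
  per scale from a seeded uniform [−1,1]³ initial condition shared across
  scales; every node is summarized.  Nodes in the same strongly coupled
  cluster synchronize to a common trajectory, so cluster membership — the
  class signal — is imprinted directly on the features.

Features for sample-classification tasks are computed transductively on
the full coupled system before cross-validation splits: the coupling ties
all samples together, so per-fold recomputation would change every
sample's features.  The implication — test samples influence training
features through the shared dynamics, though labels never do — is
inherent to the design and worth remembering when reading the scores.

## Learning and evaluation

Stratified k-fold cross-validation repeated over seeds {0..9}; aggregate
metrics are means over folds × seeds.  Accuracy, macro one-vs-rest
sensitivity and specificity, and balanced accuracy (mean per-class
recall) from the confusion matrix.  Classifiers at conventional defaults:
KNN k=5 (on standardized features — KNN is scale-sensitive and trajectory
statistics span orders of magnitude; the scaler is fit on training folds
only), random forest with 100 trees, gradient boosting with 100 depth-3
stages.  Flexibility regression is per-protein in-sample ordinary least
squares with intercept, scored by the Pearson correlation between fitted
and reference values, as in the Gaussian-network-model literature; a CV
variant is intentionally not the default.  Residue-similarity scores use
the standard published definition: residue score = summed distance to all
out-of-class samples, normalized by its maximum over the data set;
similarity score = mean of `1 − d/d_max` over classmates; both clipped to
[0,1], singleton classes get similarity 1 with a warning.

## Synchronization diagnostics

`e(t) = (1/N) Σ_i ‖x_i(t) − x̄(t)‖` measures deviation from the ensemble
mean.  Regime **full**: post-transient mean `e < 10⁻³` (absolute units).
Pairwise post-transient mean distances, normalized by the typical
trajectory amplitude, define a cluster graph at threshold 10⁻²;
**partial** requires a cluster of ≥2 nodes, otherwise **none**.  These
tolerances cleanly separate the three regimes on the fixtures; they are
diagnostic conventions, not physical constants.

## Synthetic study conditions

The generators emulate the shapes of the real applications without any
downloads; all are pure functions of (parameters, seed).

* **regular_polygon** — 16 Lorenz nodes on a hexadecagon; with ε=1.1 the
  radius-thresholded couplings at α = 0.2 / 0.6 / 1.0 (circumradius 1)
  produce independent chaos / partial synchronization / full
  synchronization.
* **chain_cloud** — 120-node chains; the folded fraction is a compact
  self-avoiding coil (confinement radius 0.55·n^{1/3} bond lengths,
  chosen to give the dense contact structure that characterizes a folded
  conformation), the rest extends away as a jittered straight tail.
  Fractions 1, 2/3 (80 folded + 40 unfolded) and 0 with ε = 1.1 / 1.0 /
  0.1 and contact radii 1 / 1 / 0.2 produce full / partial / no
  synchronization.
* **labeled_blobs** — unit-variance Gaussian classes on a regular simplex
  of side `separation` (every pair of centers exactly `separation` σ
  apart, under a seeded random rotation), 300 samples by default.
  Separation 10 is cleanly separable; separation 0 is exactly chance.
* **class_signals** — channels sharing a class-specific narrow-band latent
  waveform plus independent noise (SNR 2), giving within-class |PCC| ≈ 0.8
  versus ≈ 0.03 across classes.
* **synthetic_protein** — a Cα-like compact coil (3.8 Å bonds) with
  3-residue termini dangling radially outward; the planted per-residue
  flexibility is a lightly chain-smoothed (window [0.2, 0.6, 0.2])
  decreasing function of exponential contact density at σ=3 Å, scaled to
  a crystallographic 5–50 range.  By construction it correlates with
  inverse packing at r > 0.95.

What the fixtures do **not** model: real EEG spectra (no 1/f background,
no artifacts), count-based expression noise, genuine protein secondary
structure or crystal contacts, or any label noise.  Passing pipelines on
these fixtures demonstrates that the machinery — kernels, filtration,
dynamics, features, evaluation — is correct and that the geometry→dynamics
coupling carries class/flexibility signal; it does not certify accuracy on
real data.

## Problem sizes and experiment design

The planted-flexibility study uses 100-residue chains, 5 independent
seeds, p=10 scales and 4,000 RK4 steps (1,000 discarded); with 210
features against 100 residues the in-sample fit interpolates, so the
informative comparison is against the single-scale (p=1) ablation, whose
only scale is the empty level and which therefore carries no signal —
multiscale coverage is the entire effect.  Classification studies use 300
samples (blobs) and 45 channels (signals) with 4,000-step integrations.
These sizes were chosen as the smallest that give stable, well-separated
outcomes.

## Known limitations

* Transductive features leak unlabeled test structure into training
  features (documented above).
* The filtration's binary (−1) edge weights discard weight information
  within a level; the weighted variant is available but untested against
  any reference.
* Fixed-step explicit integrators only; stiff strong-coupling settings
  need a smaller h or smaller ε, not a different solver.
* No persistence diagrams/barcodes, no simplices above dimension 3, no
  directed or information-theoretic couplings.
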