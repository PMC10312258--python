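# Methods

This note documents the models, algorithms, numerical choices and fixture
designs implemented in `tmapper`, and what the shipped tests do and do not
demonstrate.

## Neural-mass network model

Each of N brain regions holds an excitatory and an inhibitory population
described by synaptic gating variables S_E, S_I ∈ [0, 1] (fraction of open
channels):

    dS_E/dt = −S_E/τ_E + (1 − S_E) γ_E H_E(w_EE S_E − w_IE S_I + I_G) + σ ξ_E
    dS_I/dt = −S_I/τ_I + (1 − S_I) γ_I H_I(w_EI S_E − w_II S_I + I_I) + σ ξ_I

with long-range input I_G^(i) = G Σ_{j≠i} C_ij S_E^(j). The transfer
functions are sigmoidal conversions of the classic soft rectifier that keep
its parameters while saturating at the maximal firing rate r_max:

    H_p(x) = [ r_max + (u − r_max) / (1 − e^{d_p (u − r_max)}) ] / (1 − e^{−d_p u}),
    u = a_p x − b_p.

For u ≪ r_max this reduces to u / (1 − e^{−d_p u}); for large u it
plateaus at r_max; it is monotone and bounded in [0, r_max]. Near u = 0 the
expression is evaluated by its limit 1/d_p (the correction terms involve
e^{−d_p r_max} ≈ 10⁻³⁵ and underflow); exponents are clipped at ±700 to
avoid overflow at extreme inputs.

Default parameters (the standard values of the reduced Wong–Wang lineage):
τ_E = 0.1 s, τ_I = 0.01 s, γ_E = 0.641, γ_I = 1, a_E = 310 nC⁻¹,
b_E = 125 Hz, d_E = 0.16 s, a_I = 615 nC⁻¹, b_I = 177 Hz, d_I = 0.087 s,
r_max = 500 Hz, w_EE = w_IE = 2.8 nA, w_EI = 1 nA, w_II = 0.05 nA,
I_I = 0.1 nA, σ = 0.01, G ∈ [1.1, 5] nA.

The connectome C is nonnegative with a zero diagonal and is normalized so
that max_i Σ_j |C_ij| = 1, making G comparable across connectomes.

**Integration.** Stochastic Heun (predictor–corrector): with drift f and
additive noise increment η = σ √dt ξ (ξ i.i.d. standard Gaussian per state
variable per step, the same increment in predictor and corrector),

    ỹ = y + dt f(y, t) + η,
    y' = y + dt/2 [f(y, t) + f(ỹ, t + dt)] + η.

With σ = 0 this is deterministic second-order Heun; trajectories are then
seed-independent (asserted in tests, together with second-order
convergence against a dt = 10⁻⁴ reference). The default step is 1 ms.
State is **not** clipped to [0, 1] — small noise-driven excursions are left
intact — but a `clip_state` flag is available. The default initial
condition is S_E = S_I = 0.1 with a configurable burn-in discarded before
analysis; the scaled demonstration pipeline discards 10 s.

**G(t) protocols** are piecewise-linear breakpoint lists with constant
extrapolation. The shipped `configs/default_protocol.yaml` is an
illustrative 20-minute rise-and-fall waveform, not a calibrated design.

## Hemodynamics

The Balloon–Windkessel model per region, driven by S_E:

    ds/dt = S_E − κ s − γ (f − 1),      df/dt = s,
    τ dv/dt = f − v^{1/α},              τ dq/dt = f (1 − (1−ρ)^{1/f})/ρ − v^{1/α − 1} q,
    BOLD = V₀ [k₁ (1 − q) + k₂ (1 − q/v) + k₃ (1 − v)]

with κ = 0.65 s⁻¹, γ = 0.41 s⁻¹, τ = 0.98 s, α = 0.32, ρ = 0.34,
V₀ = 0.02, k₂ = 2, and k₁ = 7ρ, k₃ = 2ρ − 0.2 recomputed from ρ unless
overridden. Integration is forward Euler at the neural dt (first order;
the refinement test verifies O(dt) error decay). The initial state
(0, 1, 1, 1) is the zero-drive equilibrium: the drift vanishes there and
the BOLD read-out is exactly zero, which the equilibrium tests assert both
by invariance and by root finding from a displaced start.

Down-sampling to scanner TR (default 0.72 s) is pure nearest-sample
decimation, no anti-alias filter: the Balloon model is already a strong
low-pass. BOLD is returned unscaled and noise-free by default.

## Attractor repertoire and ground truth

Fixed points of the σ = 0 drift are computed on a uniform G grid (default
spacing 0.01; the scaled pipeline uses 0.05) by multi-start root finding
(scipy `hybr`, xtol 10⁻¹³, one polishing pass): a 3×3 lattice of
homogeneous (S_E, S_I) starts replicated across regions, continuation from
the previous grid value's roots, and optional caller-supplied starts. For
modular connectomes the package seeds every on/off combination of module
activation patterns — a homogeneous lattice alone cannot leave the
symmetric manifold and misses partial-activation states. Roots with
‖drift‖_∞ ≥ 10⁻⁹ are rejected; duplicates within 10⁻⁴ (max norm) merge.
Failures are logged, never fatal.

Stability is classified from the central finite-difference Jacobian
(step 10⁻⁶, validated against a symbolic derivative): a point is an
attractor iff every eigenvalue real part is below −10⁻⁸; the margin avoids
classifying numerically neutral centers as attractors.

Attractor **branches** are single-linkage clusters in the product of state
space and the G axis, with G affinely rescaled from the grid range to
[0, 1] (the numeric range of the gating variables) times a configurable
weight. The linkage cutoff defaults to twice the median nearest-neighbor
distance among attractor points. Both the weighting and cutoff are
implementation choices — no canonical values exist — and are exposed in
the API. Branch ids are relabeled 1..B by increasing mean excitatory
activation for determinism.

Symbolic dynamics: each sample (state, G) is assigned the branch of its
nearest repertoire point in the same product space; exact ties go to the
lowest branch id. The ground-truth transition network has the distinct
symbols as nodes, an edge i → j wherever symbol i immediately precedes j
(self-successions contribute dwell only; self-loops are excluded), and a
node measure proportional to dwell time, normalized to 1.

## Temporal Mapper

Given samples x₁…x_T with epoch labels, the digraph G̃ is built by: (1) the
standard kNN graph (default metric: Euclidean; ties at the k-th distance
break toward the smaller time index via a stable argsort); (2) removal of
edges between in-epoch temporally adjacent pairs (i, i+1) — adjacency
only, not a wider window; (3) reciprocal pruning, with surviving edges
stored as arc pairs; (4) directed temporal arcs i → i+1 within each epoch
only. δ-compression contracts the connected components of the auxiliary
undirected graph U = {(i, j) : d_G̃(i, j) ≤ δ ∧ d_G̃(j, i) ≤ δ}, where
geodesics use unit arc weights (δ is an integer hop count), unreachable
pairs have infinite distance and never merge, and duplicate sample points
are merged only through the δ rule. The block digraph inherits every
crossing arc and drops self-loops. Properties asserted in tests: blocks
partition the time indices; measures sum to 1; increasing δ never
increases the block count; δ = 0 is the identity; weakly connected
component count is invariant under compression.

Block attributes: per-block mean of the channel-mean signal, its ordinal
rank across blocks ("activation rank"), and the most common per-sample
label (count ties broken lexicographically).

Typical parameter regimes: k = 16, δ = 10 for long simulated neural series
(~1,700 TRs); k = 5, δ = 2 for empirical fMRI runs (~1,000 TRs). Both the
δ scale and the kNN density must be read against the series length: δ must
exceed the within-attractor mixing scale of G̃ but stay below the
between-attractor separation, and at short series lengths (a few hundred
TRs) transition transits span only a few hops, so δ = 10 contracts the
network to its dominant blocks (see the scaled pipeline below).

The construction is also packaged as a scikit-learn estimator
(`TemporalMapper`), with `fit` → `network_`, `digraph_`, `labels_` and
`fit_predict` semantics, so it composes with sklearn model-selection
utilities.

## Gromov–Wasserstein third lower bound

A transition network maps to a measure network (E, p): E the asymmetric
all-pairs hop-distance matrix (requiring strong connectivity, or an
explicit finite cap for unreachable pairs), p the dwell measure. The TLB
decouples the quadratic GW objective:

    TLB² = min_{C ∈ C(p,q)} Σ_ij J_ij C_ij,
    J_ij = min_{B ∈ C(p,q)} Σ_kl (E_ik − F_jl)² B_kl.

Only out-distance profiles (rows) enter J. Each inner problem is the 1-D
squared-cost optimal transport between the weighted profiles (E_i·, p) and
(F_j·, q), solved in closed form by sorting both profiles and applying the
monotone (north-west-corner) coupling of their quantile functions; segment
lookups use midpoints of the merged cumulative grids, so zero-width
segments are harmless. The outer problem is an ordinary transportation LP
solved exactly with HiGHS (one redundant marginal constraint dropped;
marginals verified to 10⁻⁹). Both TLB² and its square root are exposed —
the literature is not consistent about which scale is reported. Tests
check the inner closed form against a generic LP, the outer optimum
against exhaustive vertex enumeration of the transportation polytope,
symmetry, permutation invariance, and the lower-bound property against
sampled feasible couplings of the full GW objective.

The J matrix computation is a set of independent tasks and could be
parallelized across (i, j); at the network sizes produced here (tens of
blocks) the serial loop is already fast.

## Analytics

Recurrence plots: network mode R[t, t′] = geodesic from block(t) to
block(t′) (asymmetric — the asymmetry encodes path dependence); state mode
= Euclidean distance between samples; dFC mode = Euclidean distance
between Fisher-z-transformed lower-triangle entries of Pearson correlation
matrices in sliding windows (default 30 TRs, step 1, windows aligned to
their first TR; zero-variance channels contribute zero correlation with a
logged warning). Source distance = row mean, sink distance = column mean
(diagonal excluded — self-distance zero would bias small networks), with
an optional division by the maximum distance; their difference sums to
zero over time points.

Cycle enumeration follows the shortest-path-pair heuristic: for each node
pair, concatenate the two shortest paths (avoiding endpoint repetition),
keep only simple cycles, deduplicate rotations keeping the copy starting
at the smallest node. The result is deliberately a *subset* of all simple
cycles (verified against exhaustive enumeration); pairs unreachable in
either direction are skipped so the heuristic works on any digraph.

Occupancy tables rank nodes by total degree (in + out) by default —
configurable to in-, or out-degree — take the top x% (floor; an empty
selection raises), and report per-label fractions of member time points;
cycle occupancy restricts to cycles through the top nodes, excludes the
top nodes' own members, and bins by cycle length.

Surrogates: `permute` shuffles time indices uniformly within each epoch
(rows move as units); `phase_randomize` draws random Fourier phases per
channel and epoch with DC and Nyquist bins kept real, preserving each
amplitude spectrum exactly. All surrogate generation is seeded.

## Synthetic fixtures and what they show

**Toy hysteresis system.** dx/dt = rate · (x − x³ + g(t)) + noise·ξ, with
a triangle-wave forcing g(t) of amplitude g_max and period P. For
|g| < g_c = 2/(3√3) ≈ 0.385 the system is bistable; at |g| = g_c a
saddle-node annihilates one attractor and the state jumps. Defaults:
g_max = 0.6, P = 125 s, 4 periods, integration step 5 ms, sampling step
0.25 s (2,001 samples), rate = 40, noise = 0.2, and an embedding of the
scalar state into 6 channels via a fixed random unit vector plus isotropic
observation noise 0.1. The trajectory starts on the lower branch so each
period yields exactly two transitions at the analytically known forcing
levels ±g_c; the ground-truth network is the two-node mutual digraph with
the dwell measure computable in closed form.

Two design choices matter and were fixed while designing the fixture:

- *Time-scale separation* (rate = 40): the reconstruction method assumes
  relaxation within an attractor is fast relative to the control sweep.
  At rate ≈ 1 the slow passage near the saddle-node ghost litters the gap
  between branches with mid-transit samples; these form reciprocal-kNN
  bridges and δ-compression then merges the two branches.
- *Multichannel embedding with observation noise*: a raw densely sampled
  1-D trajectory is a filament whose reciprocal-kNN graph is globally
  connected, so any δ ≥ 1 chains the whole manifold into one block. The
  embedded noisy cloud — the regime actual multichannel recordings occupy —
  makes each attractor branch a compact blob with a connected reciprocal
  neighborhood, separated from the other branch.

The fixture's reconstruction uses k = 16, δ = 2. On these data the
reconstruction lands at TLB ≈ 0.10–0.53 from the truth while 100
time-permuted surrogates concentrate near 0.70 (and analogously for the
recurrence-plot L2 distance), which is the basis of the null-model
acceptance test. What passing shows: the construction recovers a known
two-attractor hysteresis loop from noisy multichannel observations and is
clearly separated from temporally destroyed surrogates. What it does not
show: performance on systems with many attractors, non-stationary noise,
or real measurement confounds.

**Surrogate connectomes.** The default generator (N = 66) draws a
symmetric nonnegative matrix with log-normal weights and distance-decaying
connection density on a ring, zero diagonal, guaranteed ring connectivity,
∞-norm normalized. A modular mode (used at small N) scales log-normal
weights by `within`/`between` factors over contiguous modules. Modularity
is what makes a 10-region model support partial-activation attractors:
each module has its own fold under G, mimicking how community structure in
real connectomes underlies multistability. A homogeneous small connectome
supports only the all-low/all-high pair.

**Scaled demonstration pipeline** (`demo_transition_pipeline`): 10 regions
in 3 modules, 2 simulated minutes at dt = 1 ms, BOLD, TR = 0.72 s (167
TRs), repertoire on G ∈ [1.1, 5] step 0.05 (14 branches), ground-truth
symbols at the TR grid, Temporal Mapper with k = 16, δ = 10 on both the
down-sampled neural activity and the BOLD series. The G protocol makes two
arousal sweeps 5 → 1.15 → 5 dipping below the fold of the fully active
branch (≈ 1.3), so the trajectory repeatedly collapses part-way down the
attractor cascade and is re-recruited — the all-low state is globally
stable at every G (zero input ⇒ zero drive), so a sweep that fell to it
would never recover; the protocol must ride the hysteresis loop. The first
10 s are discarded as burn-in. At 167 TRs, δ = 10 contracts the network
onto its dominant block (every revisited regime pair is mutually within 10
hops), so the > 80 % ground-truth agreement of the acceptance test is
carried by the dominant attractor's dwell (≈ 0.88); at δ ≤ 5 the same
pipeline resolves multiple blocks with agreement ≈ 0.95. The problem sizes
(10 regions, 2 minutes, 167 TRs, G step 0.05) are the package's
desk-scale demonstration conditions.

## Degenerate inputs and edge cases

- All-zero or negative connectomes, non-finite inputs, k ≥ T, TR < dt,
  and shape mismatches raise `ValueError` with specific messages.
- Non-finite states during integration and nonpositive blood volume/inflow
  raise `FloatingPointError` naming the step (and region).
- Geodesic matrices on non-strongly-connected digraphs raise and name an
  unreachable pair unless a finite cap is supplied; the surrogate
  comparison uses cap = block count (one more than any attainable hop
  distance).
- Epoch labels must form contiguous runs; labels and epochs must cover all
  samples.

## Known limitations

- Fixed-point attractors only: no limit cycles or chaotic sets are sought,
  and branch endpoints are not classified by bifurcation type.
- The cycle heuristic is not exhaustive by design; cycle counts are lower
  bounds.
- The TLB is a lower bound of the GW distance, not the distance itself;
  couplings are soft correspondences, not graph matchings.
- The Euler hemodynamic integrator is first order; halve dt for tighter
  BOLD accuracy.
- Repertoire completeness depends on the start set: root finding can only
  report basins it reaches. The module-pattern starts cover module on/off
  combinations, not arbitrary mixed states.
- No fMRI preprocessing, atlas handling, or parameter fitting to data.
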