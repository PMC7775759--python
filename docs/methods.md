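# Methods

## Model

Each binary feature evolves independently on an L×L square lattice with
periodic boundary conditions; each cell holds one language's value
(present/absent).  A single event selects a uniform random cell and then:

* with probability 1−q, a **vertical** event: an absent feature is
  gained with probability p_I, a present feature lost with probability
  p_E;
* with probability q, a **horizontal** event: the value of a uniformly
  chosen von Neumann neighbor is copied in, with absence miscopied as
  presence with probability p_I′ and presence miscopied as absence with
  probability p_E′.

All five parameters are probabilities per event; only their ratios
matter for the stationary state.  A *sweep* is defined as L² events.
Periodic boundaries are used because the closed-form stationary solution
assumes translational invariance; edges would otherwise contaminate the
isogloss statistics.

The lattice is initialized with each cell independently present with
probability 1/2.  Faithful vertical events never change the state, which
is why the temperature τ = [(1−q)p + qp′] / [q(1−p′)] counts mutation
events against faithful *horizontal* transmission only.

## Stationary theory and numerics

The stationary frequency and isogloss density are

    ρ = [(1−q) p_I + q p_I′] / [(1−q) p + q p′]
    σ = 2 H(τ) ρ (1−ρ),   H(τ) = π(1+τ)/(2 K(1/(1+τ))) − τ.

K is the complete elliptic integral of the first kind in the **modulus**
convention (K(0) = π/2, divergent at 1).  Numerical libraries disagree
on whether the argument is the modulus k or the parameter m = k²; to be
immune to that trap we evaluate K directly by the arithmetic–geometric
mean, K(k) = π / (2·AGM(1, √(1−k²))), which converges quadratically to
machine precision.  The convention is additionally guarded by a test
comparing H evaluated at published temperatures against σ/(2ρ(1−ρ))
formed from the corresponding published summary statistics (agreement
<1.5% mid-range; the parameter convention would be off by >15%).

H is strictly increasing on (0, ∞) with range (0, 1).  Inversion is by
Brent's method on log₁₀ τ over [10⁻⁹, 10⁶] with near-machine tolerances;
round-trip accuracy is ≤10⁻⁶ relative over τ ∈ [10⁻⁶, 10³] (tested).
Degenerate observations are flagged, never clamped: H_obs ≤ 0 → τ = 0,
H_obs ≥ 1 → τ = +∞ (the feature sits on or beyond the random-field
parabola σ = 2ρ(1−ρ)), ρ ∈ {0, 1} → error (temperature undefined).

Two numerical limits worth knowing:

* H → 0 as τ → 0 only **logarithmically**, H ≈ π / (2 ln(4/√(2τ))) —
  H(10⁻⁶) ≈ 0.198, not "small".  Consequently the inversion is
  increasingly ill-conditioned for cold features: a 1% error in H_obs
  moves τ by ~10% at τ = 0.01 and by factors near τ = 10⁻⁵.
* Published per-feature medians are medians of each quantity separately;
  since the map (ρ, σ) → τ is nonlinear, inverting median ρ and median σ
  reproduces a published median τ only approximately (~1% mid-range,
  worse at the extremes).  Validation against published values is
  therefore restricted to mid-range features plus a full rank-order
  check (Spearman ≥ 0.99 over all 35).

## Simulation choices

The event loop is a numba-compiled kernel (~10⁷ events/s on one core).
Reproducibility: every `LatticeState` owns a seeded numpy Generator;
each kernel call is seeded from it, so fixed seeds give bit-identical
trajectories.  Defaults: L = 100, burn-in 5000 sweeps, 20 samples spaced
10 sweeps, 5 independent replicas (replica r seeded seed+r).  Standard
errors are computed between replica means, which absorbs within-replica
autocorrelation.  Under these conditions the simulated (ρ, σ) agree with
the analytic solution within 3 standard errors over τ ∈ {0.01, 0.1, 1,
2} and for directed (asymmetric) horizontal errors (tested at
p_I = p_E = 0.05, p_I′ = 0.02, p_E′ = 0.08, q = 0.7).

Mixing is slow as τ → 0 (the noise-free voter model coarsens only
logarithmically): the validated grid is restricted to τ ≥ 0.01, and
`estimate_stationary_summary` warns below it.  Ordered-field behavior at
τ ≈ 0 is exercised on a small lattice (L = 12) with a 50 000-sweep
burn-in, where the field genuinely orders.

## Empirical estimation

ρ is the fraction of languages attesting the feature.  σ is the fraction
of disagreeing **directed** (focal, neighbor) pairs over the k = 10
geographically nearest neighbors of each language — every language
contributes exactly k pairs, so mutual pairs may count twice; the
statistic is invariant under global relabeling and input-order
permutation (points are canonically sorted by id; distance ties then
break by index).  Distances are great-circle (haversine) on a unit
sphere; only the ordering matters, so the Earth radius never enters.
Self-exclusion is by index, not by coordinates: duplicated coordinates
are legitimate zero-distance neighbors.

Uncertainty is a nonparametric bootstrap (default B = 1000): each
replicate resamples the n languages with replacement and recomputes
everything, including neighborhoods, within the replicate.  Replicates
with σ_b ≥ 2ρ_b(1−ρ_b) have τ_b = +∞; they are retained in the
replicate arrays (rank statistics see +∞), and excluded from the median
only when below 5% of B, otherwise the summary is flagged.  The (ρ, σ)
confidence ellipse is the normal-approximation ellipse from the
bootstrap covariance at the χ²(2) quantile.

Two documented biases of this estimator:

* **k-NN shell mixing**: k = 10 neighborhoods on a (near-)grid include
  second and farther shells, inflating σ relative to the bond definition
  and biasing absolute τ̂ upward by a factor of ~2–4 in the cold-to-mid
  range.  Rank order across features is preserved (tested across two
  decades of τ).  For fully sampled synthetic grids an exact von Neumann
  bond mode reproduces lattice σ exactly and recovers τ without this
  bias; its bootstrap resamples focal cells while keeping each cell's
  neighbor values from the full field, since the grid adjacency is a
  property of the field rather than of the resample.
* **Bootstrap duplicate agreement**: resampled duplicates are mutual
  zero-distance neighbors, injecting ~6% guaranteed-agreement directed
  pairs per replicate at k = 10 (the expected extra copies of a point
  drawn at least once).  For spatially structured features this cools
  replicates slightly; for a spatially *random* feature it keeps
  replicate τ_b large but finite (~2–3) even though the point estimate
  is essentially infinite.  The point estimate is the sharp diagnostic
  for hot features; the bootstrap supplies spread.

The two-hemispheres test estimates τ independently on the subsets west
and east of configurable meridians (default west = longitude ∈ [−180°,
−30°)) and reports the Spearman correlation of the two temperature
vectors — a check that the signal is not driven by one macro-area.

## Atlas ingestion

Wide (one column per feature) and long ((language, feature, value)
triples) delimited exports are auto-detected.  Malformed coordinates are
flagged, not dropped; flagged rows are excluded from feature samples
with a log entry.  Binarization is config-driven YAML mapping each
feature's categorical codes to present/absent/excluded; the packaged
rules for the 35 reference features are our own reconstruction from the
WALS value inventories and are meant to be edited — the originally used
scheme is not public.  Unmapped codes are hard errors naming the code;
"excluded" mappings are deliberate drops.  Language exclusion lists
(e.g. sign languages, which carry no areal signal on this substrate) are
applied before the minimum-sample filter (default ≥300 languages,
boundary inclusive).  All filtering decisions are returned and logged;
nothing is dropped silently.

## Synthetic data

The generator runs the lattice to stationarity at a requested τ,
realized through the analytically exact special case q = 1,
p_I′ = p_E′ = τ/(2(1+τ)) (so the stationary frequency is 1/2 and the
theory is exact for the generating process), samples n distinct cells,
and maps them into a small latitude/longitude window (default ±10°, cell
centers plus uniform jitter at 10% of the spacing).  The window is small
enough that sphere curvature cannot reorder grid adjacency under the
haversine metric; jitter breaks distance ties.  A spatially independent
Bernoulli generator (`noise_atlas`) provides the infinite-temperature
limit.

What the synthetic atlases deliberately do **not** emulate: real
coastline/population geography, extremely uneven sampling density,
language families and their correlated histories, polyvalent features,
or feature–feature interactions.  Passing recovery tests therefore shows
the inference chain is consistent with its own generative model — not
that WALS data satisfy that model.

## Comparison utilities

Spearman correlation uses average ranks; the two-sided P-value is exact
(full enumeration of pairings) for n ≤ 10 and the t-approximation
otherwise.  The outlier-pruning regression iteratively fits OLS and
removes the point with the largest squared residual (ties broken by
label order), returning the removal order and the non-increasing SSR
trajectory; the number of removals is always an explicit argument (an
advisory elbow heuristic is provided but never applied by default,
since any fixed stopping rule would be arbitrary).  The regression is
run on log₁₀ τ by default (configurable: rank or raw), matching the
logarithmic spread of temperatures.

## Problem sizes used in validation

Simulation–theory agreement: L = 100, burn-in 5000 sweeps, 20 samples ×
5 replicas per parameter set.  Estimator recovery: L = 64 fully sampled
(n = 4096), B = 200 bootstrap replicates, true τ ∈ {0.01, 0.1, 1}.
Hemisphere and comparison checks run on smaller synthetic fixtures
(L = 24–40).  These sizes give standard errors small enough for the
3-SE / 3-interval-width criteria while keeping the whole suite fast.

## Known limitations

* Absolute temperatures from k-NN neighborhoods are biased (rank order
  is the meaningful output); calibrating the bias would require matching
  the empirical sampling geometry per feature.
* Cold features (τ ≲ 10⁻³) have large multiplicative uncertainty due to
  the logarithmic flatness of H near 0.
* The stationarity assumption is untestable from a single synchronic
  snapshot; temperatures are meaningful under the model's assumptions.
* The packaged binarization rules are reconstructions; users supplying a
  real atlas export should review them feature by feature.
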