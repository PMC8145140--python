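# Methods

## Model and procedure

The pipeline detects hotspots among N planar point events and scores each
one with a reliability in [0, 1].

**Clustering.** Extended fuzzy c-means with circular volume prototypes.
Cluster i is (vᵢ, rᵢ); the dissimilarity of event j is
δᵢⱼ = max(0, ‖xⱼ − vᵢ‖ − rᵢ), zero anywhere inside the circle. The
alternating updates minimize Σᵢⱼ uᵢⱼ^m δᵢⱼ²:

- center: vᵢ = Σⱼ uᵢⱼ^m xⱼ / Σⱼ uᵢⱼ^m;
- fuzzy covariance: Pᵢ = Σⱼ uᵢⱼ^m (xⱼ−vᵢ)(xⱼ−vᵢ)ᵀ / Σⱼ uᵢⱼ^m;
- radius: rᵢ = det(Pᵢ)^(1/n) (n = 2) in the default `as-printed` mode, or
  det(Pᵢ)^(1/2n) in `half` mode, then scaled by β/C;
- membership: the standard FCM update with exponent 2/(m−1) where all
  δᵢⱼ > 0; an event lying inside φⱼ ≥ 1 circles splits its membership
  equally among those clusters. Either branch keeps every column of U
  summing to 1.

The cluster count starts at C₀ and only decreases. Each iteration the most
similar pair under the inclusion index
Sᵢₖ = Σⱼ min(uᵢⱼ, uₖⱼ) / min(Σⱼ uᵢⱼ, Σⱼ uₖⱼ) is merged by row addition
(which preserves column sums) when the running maximum similarity S* has
stabilized (|S* − S*_prev| < η) and exceeds α = 1/(C−1). β starts at 1 and
rises toward C (releasing prototype volume gradually); a merge leaves β
unchanged. Iteration stops when max |ΔU| ≤ ε with no merge or drop in that
iteration, or at the iteration cap (flagged unconverged). At C = 2, α = 1,
so a merge to a single cluster can never fire; the run then keeps at least
two clusters by construction.

**Reliability.** Each cluster, as a fuzzy set over all N events, gets the
normalized De Luca–Termini entropy H = (1/N) Σⱼ h(uᵢⱼ) with
h(u) = −u log₂u − (1−u) log₂(1−u) (0·log 0 := 0), and reliability
R = 1 − H. The membership standard deviation reported alongside is the
population standard deviation (divide by N) over the same N events.

**Classification.** Low/Mean/High via the fixed scheme
Low = [0, 0.45), Mean = [0.45, 0.6], High = (0.6, 1], or via exact
Fisher–Jenks natural breaks (dynamic program over the sorted values;
deterministic, matches exhaustive search on small inputs). Breaks from the
Jenks route are reported as midpoints between adjacent boundary values so
reclassifying the inputs reproduces the optimal grouping.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| m | 2.0 | — | fuzzifier; >1, larger = softer memberships |
| ε | 1e−4 | membership | stop when max abs. change of U is ≤ ε |
| η | 0.01 | similarity | merge only after S* stabilizes within η |
| C₀ | 30 | — | initial cluster count; merges go downward only |
| max_iterations | 200 | — | cap; exceeded runs are flagged unconverged |
| radius_exponent_mode | as-printed | — | det^(1/n) vs det^(1/2n) |
| beta_update_mode | pseudocode | — | when β increments (see below) |

m = 2, ε = 1e−4 and η = 0.01 are the conventional fuzzy-clustering choices;
all are surfaced in `EFCMConfig`. U is initialized column-wise from a
seeded uniform RNG and renormalized; the centers then follow from the
center update.

## Numerical and design choices

- **Radius exponent.** det(P)^(1/n) with n = 2 has units of area: for an
  isotropic spread σ it equals σ² meters. Kept as the default for fidelity,
  but at metre scales it makes radii either engulf the study region
  (σ > 1 m) or vanish (σ < 1 m); all quantitative synthetic experiments in
  this package therefore run with `radius_exponent_mode="half"`, which
  yields a length (σ for an isotropic cluster).
- **β placement.** The operational rule increments β only when the
  similarity has stabilized *below* the merge threshold
  (`pseudocode` mode, default); `equation9` mode instead increments
  whenever an unmerged S* exceeds the threshold. Both are implemented;
  on the benchmark fields they behave nearly identically.
- **Merge bookkeeping.** S*_prev compares the *maximum* similarity across
  consecutive iterations (index pairs shift after merges); ties for the
  most similar pair break to the lexicographically lowest (i, k).
- **Degenerate clusters.** A cluster with zero total membership is dropped,
  C decremented and the event logged, rather than aborting.
- **Membership-update overflow.** Distances small enough that the
  inverse-power weights overflow are resolved to their mathematical limit
  (all mass on the overflowing entries, split equally).
- **Convergence flag.** An iteration that merged or dropped a cluster never
  sets convergence, even if max |ΔU| was small before the merge: a merge is
  itself a change of U.
- **Constant regression inputs.** A constant predictor raises (slope
  unidentifiable); a constant response returns R² = 0 with a warning.
- **Projection.** Clustering requires planar meters. Lat/lon input is
  projected to the UTM zone of the data centroid with a 6th-order Krüger
  transverse Mercator (round-trip error < 1e−9 degrees; northing checked
  against numeric integration of the meridian arc). Which projection
  underlies the published km² areas is not stated anywhere; UTM is this
  package's assumption. Raw-degree clustering is refused unless the input
  is declared planar.

## Synthetic data: what it emulates and what it does not

`synth` generates isotropic 2-D Gaussian event clusters plus uniform
background noise over a bounded box — the structure the method assumes
(compact event concentrations over a study region). Isotropy matches the
circular prototypes. The reference recovery conditions
(`recovery_benchmark_config`) are a 10 × 10 km box, blob σ = 100 m,
pairwise separation 1000 m = 10σ, 150 events per blob, 2% noise, with
C₀ = 2k + 2 for k blobs — neighborhood-scale hotspots inside a city-sized
region, at the lower edge of the well-separated regime.

Real patient-residence data differ in ways the generator does not model:
population density gradients, anisotropic street-network geometry,
spatially varying reporting rates, and temporal drift. Passing the
synthetic tests shows the estimator recovers the generating process it
assumes; it does not certify performance on real event fields.

## Known limitations

- **Merge stalling outside the overlap regime.** Cluster-count selection
  works by merging *overlapping* redundant prototypes: the inclusion index
  of two clusters that share no events is near zero. When blobs are
  separated far beyond ~10σ, or when background noise is absent (shared
  fractional memberships, which keep duplicate prototypes similar, vanish),
  duplicates on one blob polarize into disjoint halves with similarity
  ≈ 0.35–0.45 — below α = 1/(C−1) = 0.5 at C = 3 — and the run stalls above
  the true count. This is a property of the adaptive threshold at small C,
  not of the implementation; in the published use case (C ≈ 24,
  α ≈ 0.04) the threshold is far less demanding. Users clustering very
  sparse, widely separated fields should start from a larger C₀ or inspect
  the trace for a stalled S*.
- **Two-cluster entropy symmetry.** With exactly two final clusters, the
  columns of U sum to 1, so u₂ⱼ = 1 − u₁ⱼ and the symmetry h(u) = h(1−u)
  makes both clusters' entropies — and hence reliabilities and membership
  standard deviations — *exactly* equal. Per-hotspot reliability contrasts
  are only informative for C ≥ 3.
- **Noise drag on centers.** Background events in a cluster's catchment
  shift its weighted center by an absolute offset set by the noise fraction
  and box geometry (~tens of meters under the benchmark conditions),
  independent of blob σ.
- **Fixed-scheme boundary.** The published class table assigns one hotspot
  with R = 0.61 to Mean although the printed rule puts values above 0.6 in
  High; the packaged fixture preserves the printed label, the classifier
  follows the printed rule, and the discrepancy is documented rather than
  resolved.
- The artifact fixes n = 2 features and circular (isotropic) prototypes;
  ellipsoidal prototypes and higher-dimensional feature spaces are out of
  scope.

## Problem sizes used in the shipped experiments

Unit and acceptance tests run on fields of 300–460 events with C₀ ∈ {6, 8}
(20 seeded recovery runs plus an 8-seed × 5-level compactness sweep), and
the membership-update oracle checks 50 random instances with C ≤ 3, N ≤ 6
against SLSQP. The full suite completes in a few seconds on one CPU.
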