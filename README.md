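# fuzzyhotspots

Circular spatial hotspot detection with a per-hotspot **reliability score**,
for epidemiologists and spatial analysts who need to know not only *where*
event density is elevated (disease cases, crimes, accidents) but *how much
to trust each detected hotspot* before acting on it.

## The method

Given N point events x₁, …, x_N (projected to planar meters), an **extended
fuzzy c-means** (EFCM) clusters them with *volume prototypes*: each cluster i
is a circle with center vᵢ and radius rᵢ, and the point-to-cluster distance
is

    δᵢⱼ = max(0, ‖xⱼ − vᵢ‖ − rᵢ),

so every event inside the circle is at distance zero. The algorithm
alternately minimizes J(U, V, r) = Σᵢ Σⱼ uᵢⱼ^m δᵢⱼ² over the C × N fuzzy
partition U (columns sum to 1) and the prototypes, with the radius derived
from the fuzzy covariance Pᵢ and released gradually through a schedule
β/C (β grows from 1 toward C). Unlike plain FCM, the cluster count is not
fixed: starting from a deliberately large C₀, the two most similar clusters
— by the inclusion index Sᵢₖ = Σⱼ min(uᵢⱼ, uₖⱼ) / min(Σⱼuᵢⱼ, Σⱼuₖⱼ) — are
merged whenever their similarity has stabilized and exceeds the adaptive
threshold α = 1/(C−1).

Each detected hotspot, viewed as a fuzzy set over the events, is then scored
with the **De Luca–Termini fuzzy entropy** built from Shannon's function
h(u) = −u log₂u − (1−u) log₂(1−u):

    H(Aᵢ) = (1/N) Σⱼ h(uᵢⱼ) ∈ [0, 1],      R(Aᵢ) = 1 − H(Aᵢ).

Reliability R is 1 when the memberships defining the hotspot are crisp
(every uᵢⱼ ∈ {0, 1}) and 0 when they are maximally ambiguous (all ½).
Reliabilities are finally classified Low / Mean / High — either with the
published fixed thresholds (Low < 0.45 ≤ Mean ≤ 0.6 < High) or with exact
Fisher–Jenks natural breaks recomputed from the data.

The package also ships the published 24-hotspot summary from a case study of
oto-laryngo-pharyngeal disease in the province of Naples (area, membership
standard deviation, reliability, thematic and expert class labels) and the
ordinary-least-squares analysis that goes with it: reliability depends
strongly on membership fluctuation (R² ≈ 0.86) but barely on hotspot area
(R² ≈ 0.13).

## Worked example

Simulate a two-blob synthetic field (150 events per blob, σ = 100 m,
centers 1 km apart, 2% background noise), detect hotspots, classify them:

```sh
$ fuzzyhotspots simulate --config field.json --out events.csv
wrote 306 events to events.csv

$ fuzzyhotspots detect events.csv --planar --out-prefix demo \
      --c0 6 --seed 7 --radius-mode half
2 hotspots (converged in 18 iterations) -> demo.csv

$ fuzzyhotspots classify demo.csv --out labeled.csv --scheme fixed
breaks=[0.45, 0.6] counts={'High': 2} -> labeled.csv
```

The report (`labeled.csv`) contains one row per hotspot:

```
 id         x         y  radius_m  area_km2  entropy  reliability class
  1 4477.6088 4978.8571   314.102    0.3099   0.0189       0.9811  High
  2 5511.3454 4966.1535   304.619    0.2915   0.0189       0.9811  High
```

Both detected circles sit within ~25 m of the generating blob centers with
radii of ~3σ. Their entropy is near zero — almost every event belongs to
its hotspot with degree ≈ 1 or ≈ 0 — so reliability is ≈ 0.98: these are
hotspots a decision maker can trust. (With exactly two clusters the two
entropies coincide by the symmetry h(u) = h(1 − u), since the second
cluster's memberships are the complement of the first's.)

The regression analysis on the packaged Naples table:

```sh
$ fuzzyhotspots analyze published.csv
reliability ~ membership std: R^2 = 0.868 (slope -16.371, n = 24)
reliability ~ area (km^2): R^2 = 0.123 (slope -0.023, n = 24)
```

i.e. the more the membership degrees of a hotspot fluctuate, the lower its
reliability — while small hotspots are *not* automatically reliable ones.

`detect` also writes a GeoJSON FeatureCollection of circle polygons (for any
web map or GIS) and a JSON run-metadata file with the full per-iteration
trace (C, β, S*, max |ΔU|).

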