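# Methods

## Scope and data model

The package models monetary grocery flows between the traffic-analysis
zones of a single region and uses them to trace a foodborne outbreak back
to a retail brand. All spatial inputs are planar kilometre coordinates;
projecting real geodata is deliberately out of scope — users supply
pre-projected centroids. Three entity tables (zones, brands, stores)
define a `Region`; everything downstream is derived from them.

## Synthetic region generator

Commercial store-location and brand-revenue data are not redistributable,
so experiments run on a seeded synthetic county emulating a German
district on a postal-zone grid. Defaults:

| parameter | default | why |
|---|---|---|
| `n_zones` | 49 | a mid-size county's postal-zone count |
| `n_brands` | 10 | the national grocery market's leading chains |
| `bbox_km` | 25 | ≈ 625 km², a typical county footprint |
| `pop_range` | 2 000–30 000 | postal-zone populations, log-uniform for heavy tails |
| `stores_per_brand_range` | 3–15 | discounter vs full-range footprint spread |
| `revenue_range` | 3·10⁷–4·10⁸ | county-scale brand revenues, log-uniform (≈ an order of magnitude spread, as in national revenue rankings) |

Zone areas come from a discrete Voronoi partition: centroids are scattered
uniformly, a 256² raster is assigned to nearest centroids, and areas are
cell counts times cell area — positive by construction and summing exactly
to the box area. Store placement is population-proportional, except that
each zone first receives one store when the total store count allows: the
modelled county, like its real counterpart, has every zone both producing
and attracting food flows, which is also what makes the ">0 % threshold
supplies all zones" statistic structural rather than incidental. Per-store
revenue is the equal split of the brand total; a `weight` column in
`stores.csv` overrides the split for users who do have store-size data.

What the generator does *not* emulate: spatial clustering of stores in
retail centres, population–area correlation, store-size heterogeneity
within a brand, and road-network detours. Results on synthetic regions
demonstrate the method's internal consistency and qualitative behaviour,
not the numeric flow statistics of any real county.

## Cost matrix

Inter-zonal costs are Euclidean centroid distances. Intra-zonal costs
(the diagonal — it must be positive, or `exp(−βc)` would not penalize the
home zone at all) offer two estimators:

- **circle**: mean distance between two uniform points in a disk with the
  zone's area, `(128/45π)·sqrt(area/π)`. Depends only on zone size.
- **lattice** (default): mean distance from a uniform consumer to the
  nearest of n stores arranged in a lattice, `0.427·λ^(−1/2)` with
  λ = n/area in stores/km². Density-aware, and strictly below the circle
  estimate at unit area for any λ ≥ 1 — the circle formula overestimates
  intra-zonal trips in dense zones.

Zones without stores fall back from lattice to circle. Both estimators
scale linearly with length, as a distance must.

`buffer_zones` restricts a region to a radius around a focal zone so that
one small gravity model per illness location can replace a single huge OD
matrix; the default radius of 30 km (> 6× the mean trip) keeps tail flows
while bounding matrix size.

## Gravity model and calibration

The doubly constrained model allocates `F_ij = A_i O_i B_j D_j e^(−β c_ij)`
with productions `O` (zone store revenues) and attractions `D`
(population share × total revenue, so Σ O = Σ D holds identically).

- **Furness balancing**: alternating row/column scaling of the seed
  `e^(−βc)`, stopping when the worst relative marginal error over positive
  marginals drops below 1e-6 (default), capped at 10 000 sweeps. IPF
  converges linearly and these instances are small, so the cap is
  generous. The (A, B) pair is only identified up to a reciprocal scale;
  we fix mean(B) = 1 over positive-attraction zones so factors are
  comparable across runs. Zero-production zones keep all-zero rows rather
  than being dropped, preserving zone indexing.
- **Hyman calibration**: β₀ = 1/target; β₁ = β₀·(modelled mean/target);
  then secant updates on (β, modelled mean), safeguarded by the bracket
  implied by the strictly decreasing mean-distance-in-β relationship
  (geometric bisection when a secant step leaves the bracket). Outer
  tolerance 0.01 km, cap 50 iterations; each outer step re-runs Furness to
  full convergence. Targets at or above the zero-deterrence mean, or at or
  below the minimum trip cost, are rejected as infeasible up front.
- The default calibration target is the 4.65 km mean home-to-supermarket
  distance from the German national mobility survey; it is a plain config
  parameter, and survey processing itself is out of scope.

Exponents are clipped at −700 so `e^(−βc)` never underflows a whole row.

## Supply network and inference

Node order is fixed as [brands…, retailer zones…] + [consumer zones…] so
matrix blocks serialize stably. Retailer zones with zero production are
excluded from the transient set — they can receive no contaminated goods,
and their exclusion keeps (I − P_Q) well conditioned. The absorbing matrix
is computed by linear solve rather than explicit inverse; for these
layered networks P_Q is nilpotent of order 2, so A = (I + P_Q)·P_R exactly,
which the tests exploit as an independent check. The generic solve is kept
so deeper chains (producer → distributor → retailer) can be added without
touching the estimator.

Likelihoods are products of up to 500 absorption probabilities, far below
double-precision underflow, so all posterior arithmetic runs in log space
with max-subtraction. A brand with zero absorption probability at any
observed zone gets posterior exactly 0 — no flooring. Argmax ties break
toward the lowest brand index and ranks use competition ranking ("1 +
number of strictly better brands"); any deterministic convention
necessarily favours some ordering, so the convention is simply fixed and
documented. An all-tied posterior therefore yields rank 1 for every brand.

## Outbreak simulation

Each outbreak draws its source from the market-share prior, then must
produce illnesses at exactly |θ| distinct zones. The conditioning
mechanism is a modelling choice: sample |θ| distinct zones without
replacement with probabilities proportional to the source's absorption
row, seed one illness in each, and distribute the remaining illnesses
multinomially over the selected zones with renormalized absorption
probabilities. This preserves the relative path probabilities of the
independent-unit transmission model while meeting the spread constraint
exactly; rejection-sampling unconstrained runs would induce a slightly
different θ distribution. Illness order is shuffled so that "first m
illnesses" prefixes are unbiased. Sources whose support is smaller than
|θ| are redrawn, capped at 100 attempts before failing loudly. Batch
seeds are spawned from the master seed via `SeedSequence`, making batches
reproducible and outbreaks mutually independent.

## Evaluation

Outbreaks are simulated on the gravity network A (taken as ground truth)
and scored on both A and the intra-zonal baseline B. Accuracy/rank curves
use nested prefixes of each outbreak's shuffled 500-illness list — nested
rather than independent subsamples, for variance reduction and
determinism — and binomial standard errors accompany each accuracy value.

On network B a brand can only explain an outbreak if it has stores in
*every* observed zone, so with sparse store patterns all brands are often
infeasible. When that happens the evaluation falls back to the prior as
the posterior (prediction = largest market share, ranks from the prior);
fallback counts are reported per grid point. This matches the baseline's
expected behaviour of plateauing near the maximum prior mass regardless
of how many illnesses are reported.

The default experiment runs 300 outbreaks per scenario; the full
1000-outbreak design is one config value away (`n_outbreaks: 1000`). The
scenario grid |θ| ∈ {5, 10, …, 45, 49} and 500 illnesses per outbreak are
the defaults.

## Known limitations

- Euclidean, not road-network, distances; population-weighted centroids
  are not supported.
- Single-brand contamination sources only; no reporting delay,
  under-reporting or case-confirmation noise.
- The lattice constant 0.427 is adopted as a fixed coefficient; the
  estimator is exact only for ideal lattice store placement.
- Synthetic-region results do not transfer numerically to real counties;
  only the structural statistics (e.g. all zones supplied at the >0 %
  threshold) and qualitative orderings (gravity ≥ baseline, wider spread
  helps, accuracy grows with evidence) are expected to generalize.
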