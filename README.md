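# gravitrace

Gravity-model last-mile food flows and Bayesian retail-brand source
inference for foodborne-outbreak traceback.

When a foodborne disease outbreak is reported at the postal-zone level,
investigators need to know where the affected consumers actually bought
their groceries — and shopping does not stop at the home zip code. This
package models the consumer–retailer "last mile" with a calibrated spatial
interaction model and uses it to identify which retail brand most likely
sold the contaminated product, given only the home zones of reported
illnesses.

It is aimed at computational epidemiologists and food-safety modellers:
everything runs on delimited-text zone/store/brand tables, and a seeded
synthetic-region generator stands in for commercial store-location and
revenue data so the whole pipeline is reproducible on any machine.

## The model

**Food flows.** Revenue flows between retailer zone *i* and consumer zone
*j* follow a doubly constrained gravity model

    F_ij = A_i O_i B_j D_j exp(−β c_ij),   Σ_j F_ij = O_i,  Σ_i F_ij = D_j

where `O_i` is the retail revenue produced in zone *i*, `D_j` the
consumption potential of zone *j* (proportional to population), and
`c_ij` the trip cost in km. Off-diagonal costs are centroid distances;
intra-zonal costs use a nearest-neighbour estimate `0.427·λ^(−1/2)` km at
store density λ (stores/km²), falling back to the classical disk formula
`(128/45π)·r` for zones without stores. The balancing factors come from
Furness iteration and β is calibrated by Hyman's method so the
flow-weighted mean trip distance matches the German mobility-survey mean
shopping distance of 4.65 km.

**Source inference.** Brands, retailer zones and consumer zones form a
layered absorbing Markov chain with canonical blocks `P_Q` (transient) and
`P_R` (absorbing). Brand→zone transitions are brand market shares; zone→
zone transitions are the gravity flow shares `p(F_ij) = F_ij / Σ_j F_ij`
(network A) or the intra-zonal identity (baseline network B). With
absorption matrix `A = (I − P_Q)⁻¹ P_R`, the posterior over source brands
given illness observations θ is

    P(b | θ) ∝ P(b) · Π_{o∈θ} A[b, o],    P(b) = rev_b / Σ rev

and the estimate is the maximum-posterior brand. A Monte Carlo simulator
generates outbreaks with a prescribed number of distinct contaminated
zones |θ|, and the evaluation module scores accuracy and mean rank of the
true brand on both networks.

## Worked example

```python
import gravitrace as gt

region = gt.generate_synthetic_region(n_zones=49, n_brands=10, seed=7)
costs  = gt.build_cost_matrix(region, intrazonal_method="lattice")
O, D   = gt.zone_revenues(region), gt.consumption_potentials(region)
bal    = gt.hyman_calibrate(O, D, costs, target_mean=4.65)
print(bal.beta, gt.mean_flow_distance(bal.F, costs))
# 0.37740669222235257 4.652264639411138

pflow = gt.flow_probabilities(bal)
stats = gt.connectivity_stats(pflow, [0.0, 0.05, 0.10])
print(stats.mean_supplied_zones, stats.intra_zonal_share)
# [49.0, 5.63265306122449, 2.6122448979591835] 0.1778909037232694
```

The calibrated deterrence parameter β ≈ 0.38 /km reproduces the 4.65 km
survey mean within the 0.01 km tolerance. At the >0 % flow-share threshold
every retailer zone supplies all 49 zones (exponential deterrence never
vanishes); above 5 % / 10 % it supplies ~5.6 / ~2.6 zones, and ~18 % of
revenue stays in the home zone.

Running the source estimator on 100 simulated outbreaks (|θ| = 20,
500 illnesses each) shows why the gravity link matters:

```python
from gravitrace.evaluation import run_scenario
shares = gt.brand_zone_shares(region)
net_A, net_B = gt.build_network_A(shares, pflow), gt.build_network_B(shares)
prior = gt.market_share_prior(region.brands)
res_A, res_B = run_scenario(region, net_A, net_B, prior, n_unique=20,
                            n_outbreaks=100, illness_grid=[5, 10, 30, 100], seed=11)
print(res_A.accuracy)   # [0.61, 0.86, 0.97, 0.99]
print(res_B.accuracy)   # [0.23, 0.23, 0.23, 0.23]
```

With gravity flows (A) accuracy climbs towards 1 as illnesses accumulate;
the intra-zonal baseline (B) stays pinned near the largest prior share.

The same pipeline is scriptable from the shell:

```bash
gravitrace evaluate --seed 7 --out out/   # full scenario sweep -> out/results.csv
```

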