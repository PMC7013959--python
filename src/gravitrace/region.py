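"""Zones, brands and stores: the regional substrate of the food-flow model.

A :class:`Region` bundles the three entity tables every downstream stage
consumes: traffic-analysis zones (planar centroids, areas, populations),
retail brands (yearly revenue totals) and individual stores (brand, home
zone, revenue).  Zone-level revenue productions ``O_i``, consumption
attractions ``D_j`` and brand-by-zone market shares are derived here.

Per-store revenue follows the equal-split convention: a brand's total
revenue divided by its store count.  Real regions would refine this with
store-size data; a per-store weight column in ``stores.csv`` (see
:mod:`gravitrace.io`) overrides the equal split when available.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "Zone",
    "Brand",
    "Store",
    "Region",
    "generate_synthetic_region",
    "zone_revenues",
    "consumption_potentials",
    "brand_zone_shares",
]


@dataclass(frozen=True)
class Zone:
    """A traffic-analysis zone (postal-zone analogue) on a planar km grid."""

    zone_id: str
    x: float  # km
    y: float  # km
    area: float  # km^2, strictly positive
    population: float  # persons, >= 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"zone {self.zone_id}: non-finite centroid")
        if not (self.area > 0 and math.isfinite(self.area)):
            raise ValueError(f"zone {self.zone_id}: area must be > 0, got {self.area}")
        if self.population < 0:
            raise ValueError(f"zone {self.zone_id}: negative population")


@dataclass(frozen=True)
class Brand:
    """A retail brand with its total yearly revenue across the region."""

    brand_id: str
    total_revenue: float  # currency units, >= 0

    def __post_init__(self) -> None:
        if self.total_revenue < 0:
            raise ValueError(f"brand {self.brand_id}: negative revenue")


@dataclass(frozen=True)
class Store:
    """A single store: a brand outlet located in one zone."""

    store_id: str
    brand_id: str
    zone_id: str
    revenue: float  # currency units, >= 0

    def __post_init__(self) -> None:
        if self.revenue < 0:
            raise ValueError(f"store {self.store_id}: negative revenue")


@dataclass
class Region:
    """Zones + brands + stores with referential integrity enforced."""

    zones: list[Zone]
    brands: list[Brand]
    stores: list[Store]
    _zone_index: dict[str, int] = field(init=False, repr=False)
    _brand_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        zone_ids = [z.zone_id for z in self.zones]
        brand_ids = [b.brand_id for b in self.brands]
        if len(set(zone_ids)) != len(zone_ids):
            raise ValueError("duplicate zone_ids")
        if len(set(brand_ids)) != len(brand_ids):
            raise ValueError("duplicate brand_ids")
        self._zone_index = {zid: k for k, zid in enumerate(zone_ids)}
        self._brand_index = {bid: k for k, bid in enumerate(brand_ids)}
        for s in self.stores:
            if s.zone_id not in self._zone_index:
                raise ValueError(f"store {s.store_id} references unknown zone {s.zone_id}")
            if s.brand_id not in self._brand_index:
                raise ValueError(f"store {s.store_id} references unknown brand {s.brand_id}")

    @property
    def zone_ids(self) -> list[str]:
        return [z.zone_id for z in self.zones]

    @property
    def brand_ids(self) -> list[str]:
        return [b.brand_id for b in self.brands]

    @property
    def n_zones(self) -> int:
        return len(self.zones)

    @property
    def n_brands(self) -> int:
        return len(self.brands)

    def zone_index(self, zone_id: str) -> int:
        return self._zone_index[zone_id]

    def brand_index(self, brand_id: str) -> int:
        return self._brand_index[brand_id]

    def store_counts_by_zone(self) -> np.ndarray:
        """Number of stores per zone, aligned to ``self.zones`` order."""
        counts = np.zeros(self.n_zones, dtype=int)
        for s in self.stores:
            counts[self._zone_index[s.zone_id]] += 1
        return counts

    def populations(self) -> np.ndarray:
        return np.array([z.population for z in self.zones], dtype=float)

    def areas(self) -> np.ndarray:
        return np.array([z.area for z in self.zones], dtype=float)

    def centroids(self) -> np.ndarray:
        return np.array([[z.x, z.y] for z in self.zones], dtype=float)


# ---------------------------------------------------------------------------
# Synthetic-region generator
# ---------------------------------------------------------------------------

# Defaults emulate a single German county on a postal-zone grid: 49 zones on a
# 25 km box (~625 km^2, close to a mid-size county), 10 grocery brands, zone
# populations log-uniform between 2k and 30k persons, brand revenues spanning
# roughly an order of magnitude, and a handful of stores per brand.
_DEFAULT_BBOX_KM = 25.0
_DEFAULT_POP_RANGE = (2_000.0, 30_000.0)
_DEFAULT_STORES_RANGE = (3, 15)
_DEFAULT_REVENUE_RANGE = (3.0e7, 4.0e8)
_VORONOI_GRID = 256


def generate_synthetic_region(
    n_zones: int = 49,
    n_brands: int = 10,
    seed: int = 7,
    bbox_km: float = _DEFAULT_BBOX_KM,
    pop_range: tuple[float, float] = _DEFAULT_POP_RANGE,
    stores_per_brand_range: tuple[int, int] = _DEFAULT_STORES_RANGE,
    revenue_range: tuple[float, float] = _DEFAULT_REVENUE_RANGE,
) -> Region:
    """Generate a seeded synthetic region.

    Zone centroids are scattered uniformly in the bounding box and areas come
    from a discrete Voronoi partition of the box (a fine raster assigned to
    nearest centroids), so areas are positive and sum exactly to the box area.
    Populations are log-uniform in ``pop_range``.  Each brand receives a
    log-uniform total revenue and a uniform store count; stores are placed in
    zones with probability proportional to population, and each store's
    revenue is the equal split of the brand total.

    Deterministic for a fixed ``seed``.
    """
    if n_zones < 2:
        raise ValueError("n_zones must be >= 2")
    if n_brands < 1:
        raise ValueError("n_brands must be >= 1")
    if bbox_km <= 0:
        raise ValueError("bbox_km must be > 0")
    for name, (lo, hi) in (
        ("pop_range", pop_range),
        ("stores_per_brand_range", stores_per_brand_range),
        ("revenue_range", revenue_range),
    ):
        if lo <= 0 or hi < lo:
            raise ValueError(f"{name} must be positive with lo <= hi, got {(lo, hi)}")

    rng = np.random.default_rng(seed)

    # Voronoi-like partition on a raster; retry until every zone owns >= 1 cell.
    g = _VORONOI_GRID
    xs = (np.arange(g) + 0.5) * bbox_km / g
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    cells = np.column_stack([gx.ravel(), gy.ravel()])
    for _ in range(100):
        pts = rng.uniform(0.04 * bbox_km, 0.96 * bbox_km, size=(n_zones, 2))
        labels = np.argmin(cdist(cells, pts), axis=1)
        counts = np.bincount(labels, minlength=n_zones)
        if counts.min() > 0:
            break
    else:  # pragma: no cover - vanishingly unlikely at grid 256
        raise RuntimeError("could not partition bounding box into non-empty zones")
    areas = counts * (bbox_km / g) ** 2

    pops = np.exp(rng.uniform(np.log(pop_range[0]), np.log(pop_range[1]), n_zones))
    zones = [
        Zone(f"Z{k:03d}", float(pts[k, 0]), float(pts[k, 1]), float(areas[k]), float(pops[k]))
        for k in range(n_zones)
    ]

    revenues = np.exp(
        rng.uniform(np.log(revenue_range[0]), np.log(revenue_range[1]), n_brands)
    )
    brands = [Brand(f"B{k:02d}", float(revenues[k])) for k in range(n_brands)]

    # Store placement.  Every zone of the emulated county both generates and
    # attracts food flows, so when the total store count allows it each zone
    # receives at least one store; remaining stores go to zones with
    # probability proportional to population.
    lo, hi = stores_per_brand_range
    store_counts = rng.integers(lo, hi + 1, size=n_brands)
    slots = np.repeat(np.arange(n_brands), store_counts)
    rng.shuffle(slots)
    p_zone = pops / pops.sum()
    n_total = len(slots)
    placements = np.empty(n_total, dtype=int)
    n_cover = min(n_zones, n_total)
    placements[:n_cover] = rng.permutation(n_zones)[:n_cover]
    if n_total > n_cover:
        placements[n_cover:] = rng.choice(n_zones, size=n_total - n_cover, p=p_zone)

    stores: list[Store] = []
    per_brand_counter = [0] * n_brands
    for bk, zk in zip(slots, placements):
        sk = per_brand_counter[bk]
        per_brand_counter[bk] += 1
        stores.append(
            Store(
                f"S{bk:02d}_{sk:03d}",
                brands[bk].brand_id,
                zones[zk].zone_id,
                brands[bk].total_revenue / store_counts[bk],
            )
        )
    stores.sort(key=lambda s: s.store_id)

    return Region(zones=zones, brands=brands, stores=stores)


# ---------------------------------------------------------------------------
# Marginals and market shares
# ---------------------------------------------------------------------------


def zone_revenues(region: Region) -> np.ndarray:
    """Production marginal O: total store revenue per zone.

    Conserves revenue: ``sum(O) == sum(brand totals)`` up to float addition.
    """
    O = np.zeros(region.n_zones)
    for s in region.stores:
        O[region.zone_index(s.zone_id)] += s.revenue
    return O


def consumption_potentials(region: Region) -> np.ndarray:
    """Attraction marginal D: zone population share times total revenue.

    D_j = pop_j / sum(pop) * REV with REV the regional revenue total, so the
    doubly constrained balance sum(D) == sum(O) holds by construction.
    """
    pops = region.populations()
    total_pop = pops.sum()
    if total_pop <= 0:
        raise ValueError("total population must be positive")
    rev = zone_revenues(region).sum()
    return pops / total_pop * rev


def brand_zone_shares(region: Region) -> pd.DataFrame:
    """Row-stochastic brand-by-zone market-share matrix.

    Entry (b, r) is the fraction of brand b's revenue generated by its stores
    in zone r.  Rows sum to 1; a brand with zero total revenue has no defined
    share vector and raises ``ValueError``.
    """
    shares = np.zeros((region.n_brands, region.n_zones))
    for s in region.stores:
        shares[region.brand_index(s.brand_id), region.zone_index(s.zone_id)] += s.revenue
    row_tot = shares.sum(axis=1)
    zero = row_tot <= 0
    if zero.any():
        bad = [region.brand_ids[k] for k in np.nonzero(zero)[0]]
        raise ValueError(f"brands with zero total store revenue: {bad}")
    shares /= row_tot[:, None]
    return pd.DataFrame(shares, index=region.brand_ids, columns=region.zone_ids)
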