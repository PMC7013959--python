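"""Cost-matrix construction: inter- and intra-zonal trip distances.

Inter-zonal costs are Euclidean centroid-to-centroid distances.  The
diagonal — the effective trip length of flows that start and end in the
same zone — is estimated either by the classical circle formula (mean
distance between two uniform points in a disk of equal area,
``128/(45π)·r``) or by a nearest-neighbour lattice estimator that also
uses the zone's store count: with store density λ (stores/km²) the mean
distance from a random consumer to the nearest store is ``0.427·λ^(−1/2)``.
The lattice estimate is the default because the circle formula ignores
store density and overestimates intra-zonal trips in dense zones.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .region import Region, Zone

__all__ = [
    "CIRCLE_COEFFICIENT",
    "LATTICE_COEFFICIENT",
    "CostMatrix",
    "LatticeDensity",
    "ZeroStoreDensityError",
    "centroid_distances",
    "intrazonal_circle",
    "intrazonal_lattice",
    "build_cost_matrix",
    "buffer_zones",
]

#: Mean distance between two uniform random points in the unit disk.
CIRCLE_COEFFICIENT = 128.0 / (45.0 * math.pi)

#: Mean consumer-to-nearest-store distance at unit store density for
#: lattice-arranged stores (printed constant of the nearest-neighbour model).
LATTICE_COEFFICIENT = 0.427


class ZeroStoreDensityError(ValueError):
    """Lattice estimator undefined for a zone without stores; use the circle
    formula instead."""


@dataclass
class CostMatrix:
    """Square, symmetric trip-cost matrix in km, with intra-zonal diagonal."""

    zone_ids: list[str]
    values: np.ndarray  # n x n, km

    def __post_init__(self) -> None:
        n = len(self.zone_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"cost matrix shape {self.values.shape} != ({n}, {n})")

    def validate(self) -> None:
        """Check the full-matrix invariants: finite, positive, symmetric."""
        v = self.values
        if not np.all(np.isfinite(v)):
            raise ValueError("cost matrix has non-finite entries")
        if not np.all(v > 0):
            raise ValueError("cost matrix entries must be strictly positive")
        if not np.allclose(v, v.T, rtol=0, atol=1e-9):
            raise ValueError("cost matrix not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.zone_ids, columns=self.zone_ids)


@dataclass(frozen=True)
class LatticeDensity:
    """Store density of a zone: stores per km²."""

    area: float
    n_stores: int

    @property
    def lam(self) -> float:
        return self.n_stores / self.area


def centroid_distances(zones: list[Zone]) -> CostMatrix:
    """Euclidean centroid distances; the diagonal is left NaN for later fill."""
    if len(zones) < 2:
        raise ValueError("need at least 2 zones")
    ids = [z.zone_id for z in zones]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate zone_ids")
    pts = np.array([[z.x, z.y] for z in zones])
    c = cdist(pts, pts)
    np.fill_diagonal(c, np.nan)
    return CostMatrix(zone_ids=ids, values=c)


def intrazonal_circle(area: float) -> float:
    """Mean distance between two uniform points in a disk of the given area.

    Returns ``128/(45π) · sqrt(area/π)`` km.
    """
    if area <= 0:
        raise ValueError(f"area must be > 0, got {area}")
    r = math.sqrt(area / math.pi)
    return CIRCLE_COEFFICIENT * r


def intrazonal_lattice(area: float, n_stores: int) -> float:
    """Nearest-neighbour intra-zonal distance for lattice-arranged stores.

    λ = n_stores / area (stores per km²); returns ``0.427 · λ^(−1/2)`` km.
    Raises :class:`ZeroStoreDensityError` when the zone has no stores — the
    caller should fall back to :func:`intrazonal_circle`.
    """
    if area <= 0:
        raise ValueError(f"area must be > 0, got {area}")
    if n_stores < 0:
        raise ValueError("n_stores must be >= 0")
    if n_stores == 0:
        raise ZeroStoreDensityError("no stores in zone; circle fallback required")
    lam = n_stores / area
    return LATTICE_COEFFICIENT * lam ** -0.5


def build_cost_matrix(region: Region, intrazonal_method: str = "lattice") -> CostMatrix:
    """Full cost matrix: centroid off-diagonal plus intra-zonal diagonal.

    ``intrazonal_method`` is ``"lattice"`` (default; zones without stores fall
    back to the circle formula) or ``"circle"``.
    """
    if intrazonal_method not in ("lattice", "circle"):
        raise ValueError(f"unknown intrazonal_method {intrazonal_method!r}")
    cm = centroid_distances(region.zones)
    counts = region.store_counts_by_zone()
    diag = np.empty(region.n_zones)
    for k, z in enumerate(region.zones):
        if intrazonal_method == "lattice" and counts[k] > 0:
            diag[k] = intrazonal_lattice(z.area, int(counts[k]))
        else:
            diag[k] = intrazonal_circle(z.area)
    np.fill_diagonal(cm.values, diag)
    cm.validate()
    return cm


#: Default buffer radius: > 6x the survey mean trip keeps tail flows while
#: bounding the OD-matrix size of per-illness gravity models.
DEFAULT_BUFFER_RADIUS_KM = 30.0


def buffer_zones(
    region: Region, focal_zone: str, radius: float = DEFAULT_BUFFER_RADIUS_KM
) -> Region:
    """Restrict a region to zones whose centroid lies within ``radius`` km of
    the focal zone's centroid (focal zone always included).

    Stores outside the retained zones are dropped, and brands left without
    any store are dropped with them.  Used to build one buffered gravity
    model per reported illness location instead of a single huge OD matrix.
    """
    if focal_zone not in region.zone_ids:
        raise KeyError(f"unknown focal zone {focal_zone!r}")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    fz = region.zones[region.zone_index(focal_zone)]
    kept = [
        z for z in region.zones if math.hypot(z.x - fz.x, z.y - fz.y) <= radius
    ]
    kept_ids = {z.zone_id for z in kept}
    stores = [s for s in region.stores if s.zone_id in kept_ids]
    live_brands = {s.brand_id for s in stores}
    brands = [b for b in region.brands if b.brand_id in live_brands]
    return Region(zones=kept, brands=brands, stores=stores)
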