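"""Layered food supply network in absorbing-Markov-chain canonical form.

The network has three layers: brand source nodes, retailer zones and
consumer zones.  Brands and retailer zones are transient states, consumer
zones are absorbing states, and the full transition matrix is written in
canonical form

    P = [[P_Q, P_R],
         [0,   I  ]]

Network A links retailer zones to consumer zones with the gravity-model
flow shares; baseline network B co-locates retail and consumption, routing
each retailer zone to its own consumer zone with probability one.  The
absorbing matrix A = (I - P_Q)^(-1) P_R gives, per transient node, the
probability that a contaminated item is eventually consumed in each zone.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gravity import FlowProbabilityMatrix
from .region import Brand

__all__ = [
    "SupplyNetwork",
    "PriorDistribution",
    "build_network_A",
    "build_network_B",
    "absorbing_matrix",
    "market_share_prior",
]

_ROW_TOL = 1e-9


@dataclass
class SupplyNetwork:
    """Canonical-form layered network: brands -> retailer zones -> consumer zones.

    ``P_Q`` is the transient-to-transient block ordered [brands..., retailer
    zones...]; only the brand-row / retailer-column sub-block can be nonzero,
    so ``P_Q`` is nilpotent of order 2.  ``P_R`` holds transitions into the
    absorbing consumer zones.  Retailer zones with zero production are
    excluded from the transient set (they can receive no contaminated goods).
    """

    brand_ids: list[str]
    retailer_zone_ids: list[str]
    consumer_zone_ids: list[str]
    P_Q: np.ndarray  # (n_b + n_r) x (n_b + n_r)
    P_R: np.ndarray  # (n_b + n_r) x n_c

    def __post_init__(self) -> None:
        nb, nr, nc = len(self.brand_ids), len(self.retailer_zone_ids), len(self.consumer_zone_ids)
        nq = nb + nr
        if self.P_Q.shape != (nq, nq) or self.P_R.shape != (nq, nc):
            raise ValueError("block shapes inconsistent with node lists")
        if np.any(self.P_Q < 0) or np.any(self.P_R < 0):
            raise ValueError("transition probabilities must be non-negative")
        total_out = self.P_Q.sum(axis=1) + self.P_R.sum(axis=1)
        if not np.allclose(total_out, 1.0, rtol=0, atol=_ROW_TOL):
            raise ValueError("every transient row must have total outflow 1")
        # layered structure: brand rows leave only into retailer columns of
        # P_Q; retailer rows leave only into P_R
        if np.any(self.P_Q[:nb, :nb] != 0) or np.any(self.P_R[:nb] != 0):
            raise ValueError("brand rows may only point at retailer zones")
        if np.any(self.P_Q[nb:] != 0):
            raise ValueError("retailer rows may only point at consumer zones")

    @property
    def n_brands(self) -> int:
        return len(self.brand_ids)

    @property
    def transient_ids(self) -> list[str]:
        return list(self.brand_ids) + [f"retail:{z}" for z in self.retailer_zone_ids]

    @property
    def absorbing_ids(self) -> list[str]:
        return list(self.consumer_zone_ids)


@dataclass
class PriorDistribution:
    """Prior probability over candidate source brands."""

    brand_ids: list[str]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (len(self.brand_ids),):
            raise ValueError("prior length must match brand list")
        if np.any(self.probabilities < 0):
            raise ValueError("prior must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("prior must sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.probabilities, index=self.brand_ids, name="prior")


def _assemble(
    brand_shares: pd.DataFrame,
    retailer_ids: list[str],
    retail_to_consumer: np.ndarray,
    consumer_ids: list[str],
) -> SupplyNetwork:
    brand_ids = list(brand_shares.index)
    nb, nr, nc = len(brand_ids), len(retailer_ids), len(consumer_ids)
    shares = brand_shares[retailer_ids].to_numpy(dtype=float)
    if not np.allclose(shares.sum(axis=1), 1.0, rtol=0, atol=_ROW_TOL):
        raise ValueError(
            "brand shares do not sum to 1 over the retained retailer zones "
            "(a brand has revenue in a zero-production zone?)"
        )
    P_Q = np.zeros((nb + nr, nb + nr))
    P_Q[:nb, nb:] = shares
    P_R = np.zeros((nb + nr, nc))
    P_R[nb:] = retail_to_consumer
    return SupplyNetwork(
        brand_ids=brand_ids,
        retailer_zone_ids=list(retailer_ids),
        consumer_zone_ids=list(consumer_ids),
        P_Q=P_Q,
        P_R=P_R,
    )


def build_network_A(
    brand_shares: pd.DataFrame, P_flow: FlowProbabilityMatrix
) -> SupplyNetwork:
    """Gravity-enriched network: retailer zones feed consumer zones with the
    calibrated flow shares.

    ``brand_shares`` is the row-stochastic brands-by-zones market-share frame;
    its columns must match the flow matrix's zone ordering.
    """
    if list(brand_shares.columns) != list(P_flow.zone_ids):
        raise ValueError("brand_shares columns must match flow-probability zones")
    active = ~P_flow.zero_rows
    retailer_ids = [z for z, a in zip(P_flow.zone_ids, active) if a]
    return _assemble(
        brand_shares, retailer_ids, P_flow.P[active], list(P_flow.zone_ids)
    )


def build_network_B(brand_shares: pd.DataFrame) -> SupplyNetwork:
    """Baseline intra-zonal network: each retailer zone feeds only its own
    consumer zone (p(F_ii) = 1); brand-to-retailer rows are identical to
    network A's."""
    zone_ids = list(brand_shares.columns)
    produced = brand_shares.to_numpy(dtype=float).sum(axis=0) > 0
    retailer_ids = [z for z, a in zip(zone_ids, produced) if a]
    eye = np.zeros((len(retailer_ids), len(zone_ids)))
    for k, z in enumerate(retailer_ids):
        eye[k, zone_ids.index(z)] = 1.0
    return _assemble(brand_shares, retailer_ids, eye, zone_ids)


def absorbing_matrix(net: SupplyNetwork) -> pd.DataFrame:
    """Absorption probabilities A = (I - P_Q)^(-1) P_R by linear solve.

    Rows are transient nodes (brands, then ``retail:``-prefixed retailer
    zones), columns are consumer zones; every row sums to 1.
    """
    nq = net.P_Q.shape[0]
    try:
        A = np.linalg.solve(np.eye(nq) - net.P_Q, net.P_R)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - layered nets are regular
        raise RuntimeError(f"(I - P_Q) singular for a layered network: {exc}") from exc
    return pd.DataFrame(A, index=net.transient_ids, columns=net.absorbing_ids)


def market_share_prior(brands: list[Brand]) -> PriorDistribution:
    """Prior over source brands proportional to total brand revenue."""
    rev = np.array([b.total_revenue for b in brands], dtype=float)
    total = rev.sum()
    if total <= 0:
        raise ValueError("all brand revenues are zero; prior undefined")
    return PriorDistribution(
        brand_ids=[b.brand_id for b in brands], probabilities=rev / total
    )
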