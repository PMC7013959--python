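"""Monte Carlo outbreak simulator on a supply network.

Each outbreak draws a true source brand from the prior, then generates
``n_ill`` illnesses at consumer zones with frequencies governed by the
source's absorption probabilities — the "plinko" view of contaminated
items falling independently through the network.  The number of distinct
contaminated zones |θ| is a hard scenario parameter: the simulator first
samples exactly ``n_unique`` distinct zones (without replacement, with
probabilities proportional to the source's absorption row), seeds one
illness in each, and spreads the remaining illnesses multinomially over
that zone set with renormalized absorption probabilities.  Illness order
is shuffled so prefixes of the observation list are unbiased subsamples.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import PriorDistribution, SupplyNetwork, absorbing_matrix

__all__ = [
    "Outbreak",
    "InfeasibleSpreadError",
    "simulate_outbreak",
    "simulate_batch",
    "outbreaks_to_frame",
]

DEFAULT_N_ILL = 500
RETRY_CAP = 100


class InfeasibleSpreadError(RuntimeError):
    """No sampled source brand reaches at least n_unique consumer zones."""


@dataclass
class Outbreak:
    """One simulated outbreak: a true source and its illness observations."""

    true_source: str
    observations: list[str]  # consumer zone id per illness, shuffled order
    unique_zones: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.unique_zones = frozenset(self.observations)

    @property
    def n_ill(self) -> int:
        return len(self.observations)

    @property
    def n_unique(self) -> int:
        return len(self.unique_zones)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "true_source": self.true_source,
                "zone_id": self.observations,
                "illness_index": np.arange(self.n_ill),
            }
        )


def _brand_absorption(net: SupplyNetwork) -> pd.DataFrame:
    return absorbing_matrix(net).iloc[: net.n_brands]


def simulate_outbreak(
    net_truth: SupplyNetwork,
    prior: PriorDistribution,
    n_ill: int = DEFAULT_N_ILL,
    n_unique: int = 20,
    seed: int | np.random.Generator = 0,
    _absorb: pd.DataFrame | None = None,
) -> Outbreak:
    """Simulate one outbreak with exactly ``n_unique`` distinct zones.

    A source whose absorption support is smaller than ``n_unique`` is
    redrawn (up to a retry cap), then the call fails with
    :class:`InfeasibleSpreadError`.
    """
    if n_unique < 1 or n_ill < n_unique:
        raise ValueError("need n_ill >= n_unique >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    absorb = _brand_absorption(net_truth) if _absorb is None else _absorb
    zone_ids = np.asarray(absorb.columns)
    A = absorb.to_numpy(dtype=float)
    brand_ids = list(absorb.index)
    if brand_ids != list(prior.brand_ids):
        raise ValueError("prior brands do not match the network's brand nodes")

    for _ in range(RETRY_CAP):
        b = int(rng.choice(len(brand_ids), p=prior.probabilities))
        row = A[b]
        if int(np.count_nonzero(row > 0)) >= n_unique:
            break
    else:
        raise InfeasibleSpreadError(
            f"no source with >= {n_unique} reachable zones in {RETRY_CAP} draws"
        )

    p = row / row.sum()
    chosen = rng.choice(len(zone_ids), size=n_unique, replace=False, p=p)
    q = row[chosen] / row[chosen].sum()
    counts = np.ones(n_unique, dtype=int)
    counts += rng.multinomial(n_ill - n_unique, q)
    obs_idx = np.repeat(chosen, counts)
    rng.shuffle(obs_idx)
    return Outbreak(
        true_source=brand_ids[b], observations=[str(z) for z in zone_ids[obs_idx]]
    )


def simulate_batch(
    net_truth: SupplyNetwork,
    prior: PriorDistribution,
    n_outbreaks: int,
    n_ill: int = DEFAULT_N_ILL,
    n_unique: int = 20,
    seed: int = 0,
) -> list[Outbreak]:
    """Simulate ``n_outbreaks`` independent outbreaks.

    Per-outbreak generators are spawned deterministically from the master
    seed, so the batch is reproducible as a whole and each outbreak is
    statistically independent of the others.
    """
    if n_outbreaks < 0:
        raise ValueError("n_outbreaks must be >= 0")
    absorb = _brand_absorption(net_truth)
    children = np.random.SeedSequence(seed).spawn(n_outbreaks)
    return [
        simulate_outbreak(
            net_truth,
            prior,
            n_ill=n_ill,
            n_unique=n_unique,
            seed=np.random.default_rng(child),
            _absorb=absorb,
        )
        for child in children
    ]


def outbreaks_to_frame(outbreaks: list[Outbreak]) -> pd.DataFrame:
    """Long-format table: one row per illness, tagged by outbreak id."""
    frames = []
    for k, ob in enumerate(outbreaks):
        f = ob.to_frame()
        f.insert(0, "outbreak_id", k)
        frames.append(f)
    if not frames:
        return pd.DataFrame(
            columns=["outbreak_id", "true_source", "zone_id", "illness_index"]
        )
    return pd.concat(frames, ignore_index=True)
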