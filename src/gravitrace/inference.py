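"""Bayesian maximum-probability-of-detection source estimator.

Given illness observations θ (a multiset of consumer zones) and the
absorbing matrix A of a supply network, the likelihood of brand b is the
product over observations of the absorption probabilities A[b, o].  The
posterior over brands is prior × likelihood, normalized; the estimate is
the posterior argmax, and the true source's usefulness is summarized by
its competition rank in the descending posterior ordering.

All products are evaluated in log space with max-subtraction: 500-term
probability products underflow double precision otherwise.  Brands with a
zero absorption probability at any observed zone get likelihood exactly 0
(log-likelihood -inf), never a floor.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .network import PriorDistribution

__all__ = [
    "PosteriorResult",
    "NoFeasibleSourceError",
    "log_likelihood",
    "posterior_over_brands",
    "posterior_from_log_likelihoods",
    "estimate_source",
    "rank_of_true",
]


class NoFeasibleSourceError(ValueError):
    """Every brand has zero posterior mass for the given observations."""


@dataclass
class PosteriorResult:
    brand_ids: list[str]
    probabilities: np.ndarray  # sums to 1
    log_likelihoods: np.ndarray  # -inf allowed
    estimate: str  # argmax brand, lowest index on ties
    rank_of: Mapping[str, int]  # competition ranks, 1-based

    def as_series(self) -> pd.Series:
        return pd.Series(self.probabilities, index=self.brand_ids, name="posterior")


def _obs_log_probs(row: np.ndarray, cols: np.ndarray) -> float:
    vals = row[cols]
    if np.any(vals <= 0):
        return float("-inf")
    return float(np.log(vals).sum())


def log_likelihood(absorb: pd.DataFrame, theta: Iterable[str], brand: str) -> float:
    """Log-likelihood of ``brand`` being the source of observations ``theta``.

    ``theta`` is a multiset of consumer zone ids: repeats multiply the
    likelihood again.  Returns ``-inf`` if any observed zone is unreachable
    from the brand.
    """
    theta = list(theta)
    col_index = {z: k for k, z in enumerate(absorb.columns)}
    try:
        cols = np.array([col_index[o] for o in theta], dtype=int)
    except KeyError as exc:
        raise KeyError(f"observation zone {exc.args[0]!r} not in absorbing set") from exc
    if brand not in absorb.index:
        raise KeyError(f"unknown brand {brand!r}")
    return _obs_log_probs(absorb.loc[brand].to_numpy(dtype=float), cols)


def posterior_from_log_likelihoods(
    brand_ids: list[str], log_prior: np.ndarray, log_lik: np.ndarray
) -> PosteriorResult:
    """Normalize prior x likelihood in log space (max-subtraction)."""
    lp = log_prior + log_lik
    finite = np.isfinite(lp)
    if not finite.any():
        raise NoFeasibleSourceError(
            "all brands have zero posterior mass for these observations"
        )
    probs = np.zeros_like(lp)
    m = lp[finite].max()
    probs[finite] = np.exp(lp[finite] - m)
    probs /= probs.sum()
    est_idx = int(np.argmax(probs))  # argmax takes the lowest index on ties
    ranks = {
        b: 1 + int(np.sum(probs > probs[k])) for k, b in enumerate(brand_ids)
    }
    return PosteriorResult(
        brand_ids=list(brand_ids),
        probabilities=probs,
        log_likelihoods=log_lik,
        estimate=brand_ids[est_idx],
        rank_of=ranks,
    )


def posterior_over_brands(
    absorb: pd.DataFrame, theta: Iterable[str], prior: PriorDistribution
) -> PosteriorResult:
    """Posterior over source brands given observations ``theta``.

    ``absorb`` must contain one row per brand of the prior (retailer-zone
    rows of the full absorbing matrix are ignored).  Raises
    :class:`NoFeasibleSourceError` when no brand can explain every
    observation.
    """
    theta = list(theta)
    col_index = {z: k for k, z in enumerate(absorb.columns)}
    try:
        cols = np.array([col_index[o] for o in theta], dtype=int)
    except KeyError as exc:
        raise KeyError(f"observation zone {exc.args[0]!r} not in absorbing set") from exc
    rows = absorb.loc[prior.brand_ids].to_numpy(dtype=float)
    ll = np.array([_obs_log_probs(rows[k], cols) for k in range(len(prior.brand_ids))])
    with np.errstate(divide="ignore"):
        log_prior = np.log(prior.probabilities)
    return posterior_from_log_likelihoods(list(prior.brand_ids), log_prior, ll)


def estimate_source(post: PosteriorResult) -> str:
    """Maximum-posterior brand (ties broken toward the lowest brand index)."""
    return post.estimate


def rank_of_true(post: PosteriorResult, true_source: str) -> int:
    """Competition rank of the true source: 1 + number of strictly better brands."""
    if true_source not in post.rank_of:
        raise KeyError(f"unknown brand {true_source!r}")
    return post.rank_of[true_source]
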