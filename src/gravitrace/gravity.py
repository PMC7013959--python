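"""Doubly constrained gravity model with Furness balancing and Hyman
calibration.

The model distributes the regional revenue total over zone pairs as

    F_ij = A_i O_i B_j D_j exp(-beta c_ij)

subject to the production constraints sum_j F_ij = O_i and attraction
constraints sum_i F_ij = D_j.  The balancing factors A_i, B_j are found by
Furness iteration (iterative proportional fitting of the seed matrix
exp(-beta c)), and the deterrence parameter beta is calibrated with
Hyman's method so that the flow-weighted mean trip distance matches an
observed survey mean.  With exponential deterrence every cell of a
balanced matrix with positive marginals is strictly positive.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import CostMatrix

__all__ = [
    "GravityInputs",
    "BalancedFlows",
    "FlowProbabilityMatrix",
    "ConnectivityStats",
    "FurnessConvergenceError",
    "HymanConvergenceError",
    "InfeasibleTargetError",
    "furness_balance",
    "mean_flow_distance",
    "hyman_calibrate",
    "flow_probabilities",
    "connectivity_stats",
]

logger = logging.getLogger(__name__)

FURNESS_TOL = 1e-6
FURNESS_MAX_ITER = 10_000
HYMAN_TOL_KM = 0.01
HYMAN_MAX_OUTER = 50

# clip exponents so exp(-beta*c) never underflows to an all-zero row
_MIN_EXPONENT = -700.0


class FurnessConvergenceError(RuntimeError):
    def __init__(self, iterations: int, last_error: float):
        self.iterations = iterations
        self.last_error = last_error
        super().__init__(
            f"Furness balancing did not converge in {iterations} sweeps "
            f"(last max relative marginal error {last_error:.3e})"
        )


class HymanConvergenceError(RuntimeError):
    def __init__(self, trace: list[tuple[float, float]]):
        self.trace = trace
        super().__init__(
            f"Hyman calibration did not converge; trace (beta, mean_km) = {trace}"
        )


class InfeasibleTargetError(ValueError):
    """Target mean distance outside the range achievable for this cost matrix."""


@dataclass
class GravityInputs:
    """Marginals, costs and deterrence parameter of one gravity model."""

    O: np.ndarray  # production marginal, currency per zone
    D: np.ndarray  # attraction marginal, currency per zone
    costs: CostMatrix
    beta: float  # deterrence parameter, 1/km

    def __post_init__(self) -> None:
        self.O = np.asarray(self.O, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.costs.zone_ids)
        if self.O.shape != (n,) or self.D.shape != (n,):
            raise ValueError("marginal lengths must match the cost matrix")
        if np.any(self.O < 0) or np.any(self.D < 0):
            raise ValueError("marginals must be non-negative")
        if self.beta < 0:
            # beta = 0 is the no-deterrence (independence) limit, useful for
            # balancing without distance decay; calibration keeps beta > 0.
            raise ValueError("beta must be >= 0")
        tot_o, tot_d = self.O.sum(), self.D.sum()
        if tot_o <= 0 or tot_d <= 0:
            raise ValueError("need at least one positive production and attraction")
        if abs(tot_o - tot_d) > 1e-9 * max(tot_o, tot_d):
            raise ValueError(
                f"marginal totals differ: sum(O)={tot_o!r}, sum(D)={tot_d!r}"
            )


@dataclass
class BalancedFlows:
    """Furness-balanced flow matrix with its balancing factors."""

    zone_ids: list[str]
    F: np.ndarray  # currency flows, n x n
    A: np.ndarray  # row balancing factors
    B: np.ndarray  # column balancing factors
    beta: float
    iterations: int
    converged: bool
    max_marginal_error: float = field(default=np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.F, index=self.zone_ids, columns=self.zone_ids)


@dataclass
class FlowProbabilityMatrix:
    """Row-stochastic flow shares p(F_ij); zero-production rows stay all-zero."""

    zone_ids: list[str]
    P: np.ndarray
    zero_rows: np.ndarray  # boolean mask of all-zero (zero-production) rows

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.zone_ids, columns=self.zone_ids)


@dataclass
class ConnectivityStats:
    """Per-threshold mean supplied-zone counts plus mean intra-zonal share."""

    thresholds: list[float]
    mean_supplied_zones: list[float]
    intra_zonal_share: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "mean_supplied_zones": self.mean_supplied_zones,
                "intra_zonal_share": self.intra_zonal_share,
            }
        )


def _marginal_error(F: np.ndarray, O: np.ndarray, D: np.ndarray) -> float:
    def side(actual: np.ndarray, target: np.ndarray) -> float:
        pos = target > 0
        if not pos.any():
            return 0.0
        return float(np.max(np.abs(actual[pos] - target[pos]) / target[pos]))

    return max(side(F.sum(axis=1), O), side(F.sum(axis=0), D))


def furness_balance(
    inputs: GravityInputs,
    tol: float = FURNESS_TOL,
    max_iter: int = FURNESS_MAX_ITER,
) -> BalancedFlows:
    """Alternate row/column scaling of exp(-beta c) until both marginals hold.

    Stops when the maximum relative marginal error over positive marginals
    drops below ``tol``.  The factor pair (A, B) is only identified up to a
    reciprocal scale; the convention here rescales so the B factors of
    positive-attraction zones average 1.
    """
    O, D = inputs.O, inputs.D
    K = np.exp(np.maximum(-inputs.beta * inputs.costs.values, _MIN_EXPONENT))
    pos_o, pos_d = O > 0, D > 0
    A = np.zeros_like(O)
    B = np.ones_like(D)

    err = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        denom_a = K @ (B * D)
        A[pos_o] = 1.0 / denom_a[pos_o]
        denom_b = K.T @ (A * O)
        B[pos_d] = 1.0 / denom_b[pos_d]
        F = (A * O)[:, None] * K * (B * D)[None, :]
        err = _marginal_error(F, O, D)
        if err < tol:
            break
    else:
        raise FurnessConvergenceError(max_iter, err)

    # fix the reciprocal-scale indeterminacy: mean of active B factors = 1
    scale = B[pos_d].mean()
    B = B / scale
    A = A * scale
    F = (A * O)[:, None] * K * (B * D)[None, :]
    return BalancedFlows(
        zone_ids=list(inputs.costs.zone_ids),
        F=F,
        A=A,
        B=B,
        beta=inputs.beta,
        iterations=it,
        converged=True,
        max_marginal_error=err,
    )


def mean_flow_distance(F: np.ndarray, costs: CostMatrix) -> float:
    """Flow-weighted mean trip distance sum(F c)/sum(F) in km."""
    F = np.asarray(F, dtype=float)
    total = F.sum()
    if total <= 0:
        raise ValueError("flows sum to zero")
    return float((F * costs.values).sum() / total)


def hyman_calibrate(
    O: np.ndarray,
    D: np.ndarray,
    costs: CostMatrix,
    target_mean: float,
    tol_km: float = HYMAN_TOL_KM,
    max_outer: int = HYMAN_MAX_OUTER,
    furness_tol: float = FURNESS_TOL,
    furness_max_iter: int = FURNESS_MAX_ITER,
) -> BalancedFlows:
    """Calibrate beta so the modelled mean trip distance hits ``target_mean``.

    Hyman's schedule: beta_0 = 1/target; beta_1 = beta_0 * (modelled mean /
    target); thereafter secant updates on (beta, mean), safeguarded by the
    bracket implied by the strict monotone decrease of the mean distance in
    beta.  Every outer iteration re-runs Furness balancing to convergence.
    """
    O = np.asarray(O, dtype=float)
    D = np.asarray(D, dtype=float)
    if target_mean <= float(np.nanmin(costs.values)):
        raise InfeasibleTargetError(
            f"target {target_mean} km at or below the minimum trip cost"
        )

    def modelled(beta: float) -> tuple[float, BalancedFlows]:
        bal = furness_balance(
            GravityInputs(O=O, D=D, costs=costs, beta=beta),
            tol=furness_tol,
            max_iter=furness_max_iter,
        )
        return mean_flow_distance(bal.F, costs), bal

    # beta -> 0 gives the independence (maximum-entropy, no deterrence) mean;
    # the target must lie strictly below it.
    m_free, _ = modelled(1e-9)
    if target_mean >= m_free:
        raise InfeasibleTargetError(
            f"target {target_mean} km >= zero-deterrence mean {m_free:.4f} km"
        )

    trace: list[tuple[float, float]] = []
    lo = hi = None  # lo: mean > target (beta too small); hi: mean < target
    beta_prev = 1.0 / target_mean
    m_prev, bal = modelled(beta_prev)
    trace.append((beta_prev, m_prev))
    if abs(m_prev - target_mean) < tol_km:
        logger.info("hyman: converged at initial beta=%.6g", beta_prev)
        return bal
    beta = beta_prev * m_prev / target_mean

    for outer in range(1, max_outer + 1):
        m, bal = modelled(beta)
        trace.append((beta, m))
        if abs(m - target_mean) < tol_km:
            logger.info(
                "hyman: converged beta=%.6g mean=%.4f km in %d outer iterations",
                beta, m, outer,
            )
            return bal
        if m > target_mean:
            lo = (beta, m) if lo is None or beta > lo[0] else lo
        else:
            hi = (beta, m) if hi is None or beta < hi[0] else hi
        # secant step with bracket safeguard
        denom = m - m_prev
        if denom != 0.0:
            cand = beta + (target_mean - m) * (beta - beta_prev) / denom
        else:
            cand = np.nan
        beta_prev, m_prev = beta, m
        in_bracket = (
            np.isfinite(cand)
            and cand > 0
            and (lo is None or cand > lo[0])
            and (hi is None or cand < hi[0])
        )
        if in_bracket:
            beta = float(cand)
        elif lo is not None and hi is not None:
            beta = float(np.sqrt(lo[0] * hi[0]))
        elif lo is not None:  # no upper bracket yet: push beta up
            beta = lo[0] * 2.0
        else:  # no lower bracket: push beta down
            beta = hi[0] / 2.0
    raise HymanConvergenceError(trace)


def flow_probabilities(bal_or_F: BalancedFlows | np.ndarray, zone_ids=None) -> FlowProbabilityMatrix:
    """Row-normalize flows into supply shares p(F_ij) = F_ij / sum_j F_ij.

    Rows of zero-production zones (all-zero flow rows) are kept all-zero and
    flagged in ``zero_rows`` so zone indexing survives into the network layer.
    The diagonal entry p(F_ii) is the intra-zonal consumption share of zone i.
    """
    if isinstance(bal_or_F, BalancedFlows):
        F, ids = bal_or_F.F, bal_or_F.zone_ids
    else:
        F = np.asarray(bal_or_F, dtype=float)
        ids = list(zone_ids) if zone_ids is not None else [str(k) for k in range(F.shape[0])]
    if np.any(F < 0):
        raise ValueError("flows must be non-negative")
    row_sums = F.sum(axis=1)
    zero_rows = row_sums <= 0
    P = np.zeros_like(F)
    P[~zero_rows] = F[~zero_rows] / row_sums[~zero_rows, None]
    return FlowProbabilityMatrix(zone_ids=list(ids), P=P, zero_rows=zero_rows)


def connectivity_stats(
    P_flow: FlowProbabilityMatrix, thresholds: list[float]
) -> ConnectivityStats:
    """Mean supplied-consumer-zone counts per flow-share threshold.

    A retailer zone supplies a consumer zone at threshold t when its flow
    share is strictly greater than t.  The home zone counts like any other,
    so at t = 0 every zone of an all-positive model supplies all n zones.
    Also reports the mean intra-zonal share, the average diagonal p(F_ii).
    """
    for t in thresholds:
        if not (0 <= t < 1):
            raise ValueError(f"threshold {t} outside [0, 1)")
    P = P_flow.P
    means = [float(np.mean((P > t).sum(axis=1))) for t in thresholds]
    intra = float(np.mean(np.diag(P)))
    return ConnectivityStats(
        thresholds=list(thresholds), mean_supplied_zones=means, intra_zonal_share=intra
    )
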