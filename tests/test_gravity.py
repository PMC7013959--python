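import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gravitrace as gt
from gravitrace.distances import CostMatrix
from gravitrace.gravity import GravityInputs, InfeasibleTargetError


def _cm(values):
    v = np.asarray(values, dtype=float)
    return CostMatrix(zone_ids=[f"z{k}" for k in range(v.shape[0])], values=v)


def ipf_oracle(seed_matrix, O, D, sweeps=10_000):
    """Brute-force iterative proportional fitting: alternate exact row and
    column scaling for a fixed large number of sweeps."""
    F = np.array(seed_matrix, dtype=float)
    for _ in range(sweeps):
        F *= np.where(F.sum(1) > 0, O / np.maximum(F.sum(1), 1e-300), 0)[:, None]
        F *= np.where(F.sum(0) > 0, D / np.maximum(F.sum(0), 1e-300), 0)[None, :]
    return F


class TestFurness:
    def test_no_deterrence_gives_independence_solution(self):
        inputs = GravityInputs(
            O=[2.0, 2.0], D=[1.0, 3.0], costs=_cm([[1, 2], [2, 1]]), beta=0.0
        )
        bal = gt.furness_balance(inputs)
        np.testing.assert_allclose(bal.F, [[0.5, 1.5], [0.5, 1.5]], atol=1e-6)

    def test_single_zone(self):
        bal = gt.furness_balance(
            GravityInputs(O=[5.0], D=[5.0], costs=_cm([[1.0]]), beta=1.0)
        )
        assert bal.F[0, 0] == pytest.approx(5.0)

    def test_mismatched_totals_rejected(self):
        with pytest.raises(ValueError, match="totals differ"):
            GravityInputs(O=[1.0, 1.0], D=[1.0, 2.0], costs=_cm([[1, 2], [2, 1]]), beta=1.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_matches_ipf_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 5)
        O = rng.uniform(0.5, 5.0, n)
        D = rng.uniform(0.5, 5.0, n)
        D *= O.sum() / D.sum()
        c = rng.uniform(0.2, 8.0, (n, n))
        c = (c + c.T) / 2
        beta = 0.5
        bal = gt.furness_balance(
            GravityInputs(O=O, D=D, costs=_cm(c), beta=beta), tol=1e-12
        )
        expected = ipf_oracle(np.exp(-beta * c), O, D)
        np.testing.assert_allclose(bal.F, expected, atol=1e-8)

    def test_marginals_satisfied_and_flows_positive(self, calibrated):
        bal, O, D = calibrated["bal"], calibrated["O"], calibrated["D"]
        np.testing.assert_allclose(bal.F.sum(axis=1), O, rtol=1e-5)
        np.testing.assert_allclose(bal.F.sum(axis=0), D, rtol=1e-5)
        assert bal.max_marginal_error < 1e-6
        assert np.all(bal.F > 0)

    def test_balancing_factor_convention(self, calibrated):
        # reciprocal-scale indeterminacy fixed by mean(B) = 1
        assert calibrated["bal"].B.mean() == pytest.approx(1.0)

    def test_zero_production_zone_keeps_zero_row(self):
        bal = gt.furness_balance(
            GravityInputs(
                O=[0.0, 4.0], D=[1.0, 3.0], costs=_cm([[1, 2], [2, 1]]), beta=0.5
            )
        )
        assert bal.F[0].sum() == 0.0
        np.testing.assert_allclose(bal.F[1].sum(), 4.0, rtol=1e-6)


class TestMeanFlowDistance:
    def test_uniform_flows(self):
        cm = _cm([[1, 2], [3, 4]])
        assert gt.mean_flow_distance(np.ones((2, 2)), cm) == pytest.approx(2.5)

    def test_concentrated_flow(self):
        cm = _cm([[1, 2], [3, 4]])
        F = np.zeros((2, 2))
        F[1, 0] = 7.0
        assert gt.mean_flow_distance(F, cm) == pytest.approx(3.0)

    def test_bounded_by_cost_range(self, calibrated):
        m = gt.mean_flow_distance(calibrated["bal"].F, calibrated["costs"])
        assert calibrated["costs"].values.min() < m < calibrated["costs"].values.max()

    def test_zero_flows_rejected(self):
        with pytest.raises(ValueError):
            gt.mean_flow_distance(np.zeros((2, 2)), _cm([[1, 2], [2, 1]]))


class TestHyman:
    def test_two_zone_closed_form(self):
        # mean(beta) = (1 + 2 e^-beta) / (1 + e^-beta) = 1.25  =>  beta = ln 3
        bal = gt.hyman_calibrate(
            [1.0, 1.0], [1.0, 1.0], _cm([[1, 2], [2, 1]]), target_mean=1.25,
            tol_km=1e-6,
        )
        assert bal.beta == pytest.approx(math.log(3), abs=1e-4)

    def test_target_at_initial_beta_is_fixed_point(self):
        # find t with modelled_mean(1/t) = t; calibrating to that target must
        # return immediately at the initial beta = 1/t
        cm = _cm([[1, 2], [2, 1]])
        O = D = [1.0, 1.0]

        def mean_at(beta):
            return gt.mean_flow_distance(
                gt.furness_balance(GravityInputs(O=O, D=D, costs=cm, beta=beta)).F, cm
            )

        t = 1.5
        for _ in range(60):
            t = mean_at(1.0 / t)
        bal = gt.hyman_calibrate(O, D, cm, target_mean=t)
        assert bal.beta == pytest.approx(1.0 / t, rel=1e-9)

    def test_calibrates_49_zone_region_to_survey_mean(self, calibrated):
        m = gt.mean_flow_distance(calibrated["bal"].F, calibrated["costs"])
        assert abs(m - 4.65) < 0.01
        assert calibrated["bal"].beta > 0

    def test_infeasible_target_above_free_mean(self):
        with pytest.raises(InfeasibleTargetError):
            gt.hyman_calibrate([1.0, 1.0], [1.0, 1.0], _cm([[1, 2], [2, 1]]), 10.0)

    def test_infeasible_target_below_min_cost(self):
        with pytest.raises(InfeasibleTargetError):
            gt.hyman_calibrate([1.0, 1.0], [1.0, 1.0], _cm([[1, 2], [2, 1]]), 0.5)

    def test_mean_distance_strictly_decreasing_in_beta(self, rng):
        pts = rng.uniform(0, 20, size=(10, 2))
        c = np.hypot(*(pts[:, None] - pts[None]).transpose(2, 0, 1))
        np.fill_diagonal(c, 0.5)
        cm = _cm(c)
        O = rng.uniform(1, 5, 10)
        D = rng.uniform(1, 5, 10)
        D *= O.sum() / D.sum()
        means = [
            gt.mean_flow_distance(
                gt.furness_balance(GravityInputs(O=O, D=D, costs=cm, beta=b)).F, cm
            )
            for b in np.linspace(0.1, 2.0, 8)
        ]
        assert all(a > b for a, b in zip(means, means[1:]))


class TestFlowProbabilities:
    def test_row_normalization_example(self):
        pf = gt.flow_probabilities(np.array([[2.0, 3.0, 5.0]] * 3), list("abc"))
        np.testing.assert_allclose(pf.P[0], [0.2, 0.3, 0.5])

    def test_zero_rows_flagged_not_dropped(self):
        F = np.array([[0.0, 0.0], [1.0, 3.0]])
        pf = gt.flow_probabilities(F, ["a", "b"])
        assert pf.zero_rows.tolist() == [True, False]
        assert pf.P[0].sum() == 0.0

    def test_calibrated_rows_sum_to_one(self, networks):
        np.testing.assert_allclose(networks["pflow"].P.sum(axis=1), 1.0, atol=1e-12)

    def test_diagonal_is_intrazonal_share(self, calibrated, networks):
        bal = calibrated["bal"]
        k = 3
        assert networks["pflow"].P[k, k] == pytest.approx(
            bal.F[k, k] / bal.F[k].sum()
        )


class TestConnectivityStats:
    def test_strict_threshold_counting(self):
        # shares come out exactly [0.6, 0.3, 0.1]; 0.1 is NOT > 0.10
        pf = gt.flow_probabilities(np.array([[6.0, 3.0, 1.0]] * 3), list("abc"))
        stats = gt.connectivity_stats(pf, [0.0, 0.05, 0.10])
        assert stats.mean_supplied_zones == [3.0, 3.0, 2.0]

    def test_identity_matrix(self):
        pf = gt.flow_probabilities(np.eye(4), list("abcd"))
        stats = gt.connectivity_stats(pf, [0.0, 0.5, 0.99])
        assert stats.mean_supplied_zones == [1.0, 1.0, 1.0]
        assert stats.intra_zonal_share == 1.0

    def test_calibrated_zero_threshold_reaches_all_zones(self, networks):
        stats = gt.connectivity_stats(networks["pflow"], [0.0])
        assert stats.mean_supplied_zones[0] == 49.0

    def test_invalid_threshold_rejected(self):
        pf = gt.flow_probabilities(np.eye(2), ["a", "b"])
        with pytest.raises(ValueError):
            gt.connectivity_stats(pf, [1.0])
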