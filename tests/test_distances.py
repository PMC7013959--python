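import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gravitrace as gt
from gravitrace.distances import ZeroStoreDensityError, centroid_distances
from gravitrace.region import Brand, Region, Store, Zone


def _zones(coords, area=1.0, pop=10.0):
    return [Zone(f"z{k}", x, y, area, pop) for k, (x, y) in enumerate(coords)]


class TestCentroidDistances:
    def test_three_four_five_triangle(self):
        cm = centroid_distances(_zones([(0, 0), (3, 4)]))
        assert cm.values[0, 1] == pytest.approx(5.0)

    def test_collinear_zones(self):
        cm = centroid_distances(_zones([(0, 0), (1, 0), (2, 0)]))
        assert cm.values[0, 2] == pytest.approx(2.0)

    def test_symmetry_on_random_layout(self, rng):
        zones = _zones(rng.uniform(0, 25, size=(49, 2)))
        cm = centroid_distances(zones)
        off = cm.values.copy()
        np.fill_diagonal(off, 0.0)
        np.testing.assert_allclose(off, off.T, atol=1e-12)

    def test_duplicate_ids_rejected(self):
        zones = [Zone("a", 0, 0, 1, 1), Zone("a", 1, 0, 1, 1)]
        with pytest.raises(ValueError, match="duplicate"):
            centroid_distances(zones)


class TestIntrazonalEstimators:
    def test_circle_formula_unit_radius(self):
        # area pi km^2 -> r = 1; mean distance between two uniform points in
        # the unit disk is 128/(45 pi)
        assert gt.intrazonal_circle(math.pi) == pytest.approx(128 / (45 * math.pi))

    def test_circle_linear_in_radius(self):
        assert gt.intrazonal_circle(4 * math.pi) == pytest.approx(
            2 * gt.intrazonal_circle(math.pi)
        )

    def test_circle_vanishes_with_area(self):
        assert gt.intrazonal_circle(1e-12) < 1e-5

    def test_circle_matches_monte_carlo_disk_oracle(self, rng):
        # 10^6 independent point pairs uniform in the unit disk
        n = 1_000_000
        pts = rng.uniform(-1, 1, size=(2 * n, 2))
        pts = pts[(pts**2).sum(axis=1) <= 1][: 2 * (n // 2)]
        a, b = pts[::2], pts[1::2]
        mc = float(np.mean(np.hypot(*(a - b).T)))
        assert gt.intrazonal_circle(math.pi) == pytest.approx(mc, abs=0.002)

    @pytest.mark.parametrize(
        "area,n_stores,expected",
        [(1.0, 1, 0.427), (1.0, 4, 0.2135), (2.0, 8, 0.2135)],
    )
    def test_lattice_values(self, area, n_stores, expected):
        assert gt.intrazonal_lattice(area, n_stores) == pytest.approx(expected)

    def test_lattice_zero_stores_signals_fallback(self):
        with pytest.raises(ZeroStoreDensityError):
            gt.intrazonal_lattice(1.0, 0)

    @pytest.mark.parametrize("fn", ["circle", "lattice"])
    def test_nonpositive_area_rejected(self, fn):
        with pytest.raises(ValueError):
            if fn == "circle":
                gt.intrazonal_circle(-1.0)
            else:
                gt.intrazonal_lattice(0.0, 3)

    @settings(deadline=None, derandomize=True)
    @given(
        area=st.floats(0.1, 1e3),
        n=st.integers(1, 200),
        scale=st.floats(1.5, 10.0),
    )
    def test_estimators_scale_linearly_with_length(self, area, n, scale):
        # doubling all linear dimensions (area x scale^2) doubles both estimates
        assert gt.intrazonal_circle(area * scale**2) == pytest.approx(
            scale * gt.intrazonal_circle(area), rel=1e-9
        )
        assert gt.intrazonal_lattice(area * scale**2, n) == pytest.approx(
            scale * gt.intrazonal_lattice(area, n), rel=1e-9
        )

    @pytest.mark.parametrize("n_stores", [1, 2, 5, 25])
    def test_lattice_below_circle_at_unit_area(self, n_stores):
        # the density-aware estimate corrects the circle formula's
        # overestimation whenever at least one store is present
        assert gt.intrazonal_lattice(1.0, n_stores) < gt.intrazonal_circle(1.0)


class TestBuildCostMatrix:
    def test_lattice_diagonal(self):
        zones = _zones([(0, 0), (10, 0)], area=2.0)
        reg = Region(
            zones,
            [Brand("x", 16.0)],
            [Store(f"s{k}", "x", "z0", 2.0) for k in range(8)]
            + [Store("t0", "x", "z1", 2.0)],
        )
        cm = gt.build_cost_matrix(reg, intrazonal_method="lattice")
        assert cm.values[0, 0] == pytest.approx(0.427 * (8 / 2.0) ** -0.5)
        assert cm.values[1, 1] == pytest.approx(0.427 * (1 / 2.0) ** -0.5)

    def test_zero_store_zone_falls_back_to_circle(self):
        zones = _zones([(0, 0), (10, 0)], area=3.0)
        reg = Region(zones, [Brand("x", 1.0)], [Store("s", "x", "z0", 1.0)])
        cm = gt.build_cost_matrix(reg, intrazonal_method="lattice")
        assert cm.values[1, 1] == pytest.approx(gt.intrazonal_circle(3.0))

    def test_matrix_strictly_positive(self, region49):
        cm = gt.build_cost_matrix(region49)
        assert cm.values.min() > 0
        assert np.isfinite(cm.values).all()


class TestBufferZones:
    def _region(self):
        zones = _zones([(0, 0), (5, 0), (15, 0)])
        brands = [Brand("x", 2.0), Brand("y", 1.0)]
        stores = [
            Store("s1", "x", "z0", 1.0),
            Store("s2", "x", "z1", 1.0),
            Store("s3", "y", "z2", 1.0),
        ]
        return Region(zones, brands, stores)

    def test_radius_beyond_diameter_keeps_everything(self):
        reg = self._region()
        sub = gt.buffer_zones(reg, "z0", 100.0)
        assert sub.zone_ids == reg.zone_ids
        assert len(sub.stores) == 3

    def test_radius_cuts_far_zones_and_their_brands(self):
        sub = gt.buffer_zones(self._region(), "z0", 10.0)
        assert sub.zone_ids == ["z0", "z1"]
        # brand y only had a store in the dropped zone
        assert [b.brand_id for b in sub.brands] == ["x"]

    def test_boundary_is_inclusive(self):
        # second-nearest centroid at exactly 5 km
        sub = gt.buffer_zones(self._region(), "z0", 5.0)
        assert sub.n_zones == 2
        sub = gt.buffer_zones(self._region(), "z0", 4.999)
        assert sub.n_zones == 1

    def test_unknown_focal_zone(self):
        with pytest.raises(KeyError):
            gt.buffer_zones(self._region(), "nope", 1.0)
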