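import numpy as np
import pytest

import gravitrace as gt


@pytest.fixture(scope="session")
def region49():
    """The default 49-zone, 10-brand synthetic county (seed 7)."""
    return gt.generate_synthetic_region(n_zones=49, n_brands=10, seed=7)


@pytest.fixture(scope="session")
def calibrated(region49):
    """Gravity model on the 49-zone region calibrated to 4.65 km."""
    costs = gt.build_cost_matrix(region49, intrazonal_method="lattice")
    O = gt.zone_revenues(region49)
    D = gt.consumption_potentials(region49)
    bal = gt.hyman_calibrate(O, D, costs, target_mean=4.65, tol_km=0.01)
    return {"costs": costs, "O": O, "D": D, "bal": bal}


@pytest.fixture(scope="session")
def networks(region49, calibrated):
    """Supply networks A and B plus the market-share prior."""
    pflow = gt.flow_probabilities(calibrated["bal"])
    shares = gt.brand_zone_shares(region49)
    return {
        "pflow": pflow,
        "shares": shares,
        "net_A": gt.build_network_A(shares, pflow),
        "net_B": gt.build_network_B(shares),
        "prior": gt.market_share_prior(region49.brands),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
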