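import numpy as np
import pytest

import airkrig as ak


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210714)


@pytest.fixture(scope="session")
def tiny_campaign():
    """A miniature campaign (2 routes, ~20 min dense sampling) for fast
    pipeline tests; one Gaussian draw, a couple hundred points."""
    spec = ak.CampaignSpec(
        routes=[
            ak.RouteSpec("a", [(-1500.0, 0.0), (1500.0, 400.0)]),
            ak.RouteSpec("b", [(0.0, -1200.0), (300.0, 1400.0)]),
        ],
        faults={
            "a": ak.SensorFaultSpec(additive=3.0, multiplicative=2.0, noise_sd=0.5),
            "b": ak.SensorFaultSpec(additive=-1.0, multiplicative=1.8, noise_sd=0.5),
        },
        duration=4 * 3600.0,
        windows=[ak.synthetic.SamplingWindow(start=3600.0, length=1200.0, interval=20.0)],
        station_xy=(50.0, 50.0),
        seed=11,
    )
    return ak.simulate_campaign(spec)


@pytest.fixture(scope="session")
def exp_model():
    return ak.VariogramModel("exponential", sill=60.0, nugget=2.0, range_=8000.0, K=100.0)


@pytest.fixture(scope="session")
def sph_model():
    return ak.VariogramModel("spherical", sill=82.30, nugget=5.00, range_=30415.43, K=105.16)


def random_neighbors(rng, n, *, scale_xy=3000.0, scale_t=600.0, base=50.0):
    """A random ObservationSet usable as a kriging neighborhood."""
    x = rng.uniform(-scale_xy, scale_xy, n)
    y = rng.uniform(-scale_xy, scale_xy, n)
    t = rng.uniform(0.0, scale_t, n)
    z = base + rng.normal(0.0, 5.0, n)
    ids = [f"s{i%3}" for i in range(n)]
    return ak.ObservationSet.from_arrays(ids, x, y, t, z, calibrated=True)


@pytest.fixture(scope="session")
def flat_station():
    """A station series that is linear in t (easy to reason about)."""
    times = np.arange(0.0, 7200.1, 3600.0)
    return ak.FixedStationSeries(x=0.0, y=0.0, times=times, values=50.0 + times / 720.0)
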