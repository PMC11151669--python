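import numpy as np
import pytest

import padfkit as pk


@pytest.fixture(scope="session")
def small_geom():
    """64-pixel detector with the standard edge q of 1.28 nm^-1."""
    return pk.DetectorGeometry.for_edge_q(64, 1.28)


@pytest.fixture(scope="session")
def hexagon():
    return pk.make_hexagon(15.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_polar_set(n, nq, ntheta, qmax=1.0, seed=0):
    """A list of random non-negative polar patterns sharing one grid."""
    rng = np.random.default_rng(seed)
    return [
        pk.PolarIntensity(values=rng.random((nq, ntheta)), qmax=qmax)
        for _ in range(n)
    ]


@pytest.fixture(scope="session")
def hex_midscale():
    """A mid-size hexagon dataset used by convergence-style tests.

    400 exposures on a 64^2 detector, polar-resampled at nq=32, ntheta=180.
    """
    geom = pk.DetectorGeometry.for_edge_q(64, 1.28)
    model = pk.make_hexagon(15.0)
    ds = pk.simulate_dataset(model, geom, 400, seed=99)
    polar = [pk.to_polar(p, geom, 32, 180) for p in ds.patterns]
    return {"geometry": geom, "model": model, "dataset": ds, "polar": polar}
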