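"""Shared fixtures: small phantoms and noiseless scans used across modules."""

from __future__ import annotations

import numpy as np
import pytest

from gbpct.acquisition import AcquisitionGeometry, simulate_stepping
from gbpct.phantom import PhantomVolume, make_phantom
from gbpct.retrieval import retrieve


@pytest.fixture(scope="session")
def disk_phantom_64():
    """Uniform disk: mu = 0.01/px, delta = 0.005, radius 0.45*64."""
    n = 64
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    disk = (yy - c) ** 2 + (xx - c) ** 2 <= (0.45 * n) ** 2
    return PhantomVolume(mu=0.01 * disk, delta=0.005 * disk)


@pytest.fixture(scope="session")
def marbled_phantom_64():
    return make_phantom((64, 64), seed=7)


@pytest.fixture(scope="session")
def noiseless_sino_64(marbled_phantom_64):
    """Noise-free retrieval of the default marbled phantom, 100 angles."""
    geo = AcquisitionGeometry(n_angles=100)
    scan = simulate_stepping(marbled_phantom_64, geo, noise=False)
    return retrieve(scan), geo


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
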