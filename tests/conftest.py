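"""Shared fixtures: synthetic phantoms, coil maps, and simulated k-space.

Fixture scales:

* 32-cube, 4 coils — cheap unit-test fixture (seconds per reconstruction).
* 64-cube, 8 coils — the default desk-scale fixture.
* (32, 128, 128), 8 coils — the trend fixture: a 128x128 phase-encode
  plane (the smallest square plane that can host a 32x32 calibration
  block at R = 15) with vessel counts scaled to the in-plane FOV.
"""

import pytest

from csmra import (
    make_coil_sensitivities,
    make_vessel_phantom,
    simulate_kspace,
)

NOISE_SIGMA = 0.01


@pytest.fixture(scope="session")
def phantom32():
    return make_vessel_phantom((32, 32, 32), n_large=1, n_small=3, tortuosity=1.0, seed=3)


@pytest.fixture(scope="session")
def sens32():
    return make_coil_sensitivities((32, 32, 32), ncoils=4, seed=1)


@pytest.fixture(scope="session")
def kspace32(phantom32, sens32):
    return simulate_kspace(phantom32, sens32, noise_sigma=NOISE_SIGMA, seed=5)


@pytest.fixture(scope="session")
def phantom64():
    return make_vessel_phantom((64, 64, 64), n_large=2, n_small=6, tortuosity=1.0, seed=7)


@pytest.fixture(scope="session")
def sens64():
    return make_coil_sensitivities((64, 64, 64), ncoils=8, seed=1)


@pytest.fixture(scope="session")
def kspace64(phantom64, sens64):
    return simulate_kspace(phantom64, sens64, noise_sigma=NOISE_SIGMA, seed=5)


@pytest.fixture(scope="session")
def trend_kspace():
    shape = (32, 128, 128)
    ph = make_vessel_phantom(shape, n_large=4, n_small=24, tortuosity=1.2, seed=7)
    sens = make_coil_sensitivities(shape, ncoils=8, seed=1)
    return simulate_kspace(ph, sens, noise_sigma=NOISE_SIGMA, seed=5)
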