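"""Shared fixtures: synthetic reflection sets and toy crystals.

Expensive reflection sets are session-scoped; every stochastic fixture
is generated from a fixed seed so the suite is fully deterministic.
"""

import numpy as np
import pytest

from anisoaudit.geometry import UnitCell
from anisoaudit.synthetic import DirectionalSigma, SimulationSpec, gen_reflections

CUBE = UnitCell(42.5, 42.5, 42.5)


def iso_tensor(b):
    return tuple(tuple(float(b) if i == j else 0.0 for j in range(3)) for i in range(3))


def diag_tensor(bx, by, bz):
    vals = (float(bx), float(by), float(bz))
    return tuple(tuple(vals[i] if i == j else 0.0 for j in range(3)) for i in range(3))


@pytest.fixture(scope="session")
def cube_cell():
    return CUBE


@pytest.fixture(scope="session")
def aniso_noise_free():
    """Noise-free reflections with an imposed diag(20, 20, 70) tensor."""
    spec = SimulationSpec(cell=CUBE, dmin=2.0, b_tensor=diag_tensor(20, 20, 70),
                          wilson_noise=False)
    return spec, gen_reflections(spec)


@pytest.fixture(scope="session")
def iso_noise_free_b30():
    """Noise-free isotropic B = 30 reflections."""
    spec = SimulationSpec(cell=CUBE, dmin=2.0, b_tensor=iso_tensor(30),
                          wilson_noise=False)
    return spec, gen_reflections(spec)


@pytest.fixture(scope="session")
def flat_snr10():
    """Flat intensities with F/sigF = 10 everywhere (sigma_frac = 0.2)."""
    spec = SimulationSpec(cell=CUBE, dmin=2.0, sigma_frac=0.2, wilson_noise=False)
    return spec, gen_reflections(spec)


@pytest.fixture(scope="session")
def zaxis_inflated():
    """F/sigF = 10 except below d = 3 A in the z cone, where it is 1."""
    spec = SimulationSpec(
        cell=CUBE, dmin=2.0, sigma_frac=0.2, wilson_noise=False,
        directional_sigma=(
            DirectionalSigma(factor=10.0, d_max=3.0, axis=(0, 0, 1), cone_deg=20.0),
        ),
    )
    return spec, gen_reflections(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
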