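"""Shared fixtures: small frequency grids and model templates.

Test problem sizes are kept small (coarse 2-Hz grids, few free parameters)
so the whole suite runs on one CPU in minutes.
"""

import numpy as np
import pytest

from spectraldcm import GaussianDensity, MassModelParams


@pytest.fixture(scope="session")
def freqs():
    """Coarse 4-100 Hz grid (2 Hz) used by most fitting tests."""
    return np.arange(4.0, 101.0, 2.0)


@pytest.fixture(scope="session")
def mass_1ch():
    return MassModelParams()


@pytest.fixture(scope="session")
def mass_2ch():
    """Two-channel observation: channel 0 reads the fast principal
    population, channel 1 the slow one."""
    return MassModelParams(Lw=((1.0, 0.0, 0.0, 0.0), (0.0, 0.0, 1.0, 0.0)))


from spectraldcm.benchmarks import linear_gaussian_problem as make_linear_problem  # noqa: E402,F401
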