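import numpy as np
import pytest

from betacell.calibration import build_mean_ca_surrogate
from betacell.metabolic import MetabolicParameters


@pytest.fixture()
def params():
    return MetabolicParameters()


@pytest.fixture(scope="session")
def glucose_grid():
    """Compact glucose-influx grid covering basal to saturating input."""
    return np.linspace(0.0, 0.4, 7)


@pytest.fixture(scope="session")
def mean_ca_surrogate():
    """Session-wide mean-Ca²⁺ surface over the calibration input range.

    Uses the package-default input grid, which spans the full glucose
    (k_ATP) and alanine (g_NaAla) condition ranges of the calibration
    designs.
    """
    return build_mean_ca_surrogate()
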