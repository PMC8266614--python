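import numpy as np
import pytest

from smkinetics import (
    MixtureModel,
    ObservationWindow,
    SimulationConfig,
    simulate_dwells,
)

# The emulated assay: 0.1 s camera frames, 3-minute recordings, and the
# two-condition amiE102 mixture estimates (no-Crc and with-Crc amplitudes on
# shared ~2 s / ~60 s lifetimes).
WINDOW = ObservationWindow(t_min=0.1, t_max=180.0)
MODEL_NO_CRC = MixtureModel([0.56, 0.44], [2.0, 60.0])
MODEL_WITH_CRC = MixtureModel([0.30, 0.70], [2.0, 60.0])
MODEL_MUTANT = MixtureModel([0.81, 0.05, 0.14], [0.4, 2.0, 60.0])
BLEACH_LIFETIME_S = 173.0


@pytest.fixture
def window():
    return WINDOW


@pytest.fixture
def model_no_crc():
    return MODEL_NO_CRC


@pytest.fixture
def model_with_crc():
    return MODEL_WITH_CRC


@pytest.fixture
def model_mutant():
    return MODEL_MUTANT


@pytest.fixture
def dwells_no_crc():
    """5000 frame-quantized dwell times from the no-Crc two-state model."""
    return simulate_dwells(
        MODEL_NO_CRC, WINDOW, SimulationConfig(n_events=5000, seed=0)
    )


def truncated_mixture_cdf(t, weights, lifetimes, t_min, t_max):
    """Independent closed-form CDF of a window-truncated exponential mixture.

    Kept here (not imported from the package) so tests that use it as an
    oracle stay independent of the code path they check.
    """
    t = np.asarray(t, dtype=float)
    w = np.asarray(weights)
    tau = np.asarray(lifetimes)
    Z = np.sum(w * (np.exp(-t_min / tau) - np.exp(-t_max / tau)))
    return np.sum(w * (np.exp(-t_min / tau) - np.exp(-t[..., None] / tau)), axis=-1) / Z
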