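import numpy as np
import pytest

from thzchem.containers import SampleGeometry
from thzchem.simulate import ClassProfile, InstrumentModel, default_wheat_profiles


@pytest.fixture
def geometry():
    return SampleGeometry(thickness_d=1.0)


@pytest.fixture
def quiet_instrument():
    """Noiseless instrument: analytic pulses, exact round trips."""
    return InstrumentModel(amplitude_noise_sd=0.0, additive_noise_sd=0.0)


@pytest.fixture
def instrument():
    return InstrumentModel()


@pytest.fixture
def clean_profiles():
    """The eight wheat-variety profiles with all random deviations off."""
    return default_wheat_profiles(
        alpha_offset_deviation_sd=0.0, alpha_deviation_sd=0.0, n_deviation_sd=0.0
    )


def planted_band_profiles(grid, signal_step=1.0, signal_base=1.0):
    """Eight classes whose only difference is a bump confined exactly to
    variables 57-64 of the given grid; everything else identical."""
    band = (float(grid[56]), float(grid[63]))
    return [
        ClassProfile(
            class_id=c,
            alpha_offset=30.0,
            alpha_slope=10.0,
            signal_band=band,
            signal_amplitude=signal_base + signal_step * (c - 1),
            alpha_offset_deviation_sd=0.0,
            alpha_deviation_sd=0.0,
            n_deviation_sd=0.0,
        )
        for c in range(1, 9)
    ]


@pytest.fixture
def grid128():
    return np.linspace(0.2, 1.5, 128)
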