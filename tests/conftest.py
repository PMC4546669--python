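import numpy as np
import pytest

from cholwave import (
    CalibrationTable,
    build_network,
    load_neuron_params,
    load_synapse_params,
)
from cholwave.experiments import reduced_spec, scaled_wie


@pytest.fixture(scope="session")
def neuron_params():
    return load_neuron_params()


@pytest.fixture(scope="session")
def synapse_params():
    return load_synapse_params()


@pytest.fixture(scope="session")
def calib():
    """Shared I_tune calibration cache (one bisection per gKs per session)."""
    return CalibrationTable()


@pytest.fixture(scope="session")
def small_net():
    """Reduced lattice with full-scale-equivalent global inhibition."""
    spec = reduced_spec()
    w = scaled_wie(20.0, spec)
    return build_network(spec, w_ie=w, w_ii=w)
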