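import numpy as np
import pytest

import denitflux as dn


@pytest.fixture(scope="session")
def registry():
    return dn.default_registry()


@pytest.fixture(scope="session")
def r4_reference(registry):
    """Rate set, schedule and phase N2O rates from the bundled R4 yields."""
    return dn.reference_inputs("R4", registry)


@pytest.fixture(scope="session")
def r32_reference(registry):
    return dn.reference_inputs("R32", registry)


@pytest.fixture(scope="session")
def sim_clean():
    """Noise-free low-frequency (R4-like) run shared across tests."""
    return dn.simulate(days=4, seed=1, noise=dn.NoiseModel.none(), burn_in_days=4.0)


@pytest.fixture(scope="session")
def report_clean(sim_clean):
    return dn.run_pipeline(
        sim_clean.clean_samples,
        sim_clean.clean_trace,
        sim_clean.config,
        sim_clean.feed_concentrations,
    )


@pytest.fixture()
def square_trace():
    """Hand-built square-wave DO trace: 4 cycles/day of 4 h up / 2 h down."""
    minutes = np.arange(1440.0)
    do = np.where((minutes % 360) < 240, 0.8, 0.0)
    zeros = np.zeros_like(minutes)
    return dn.GasTrace(
        time_min=minutes,
        y_o2=np.where(do > 0, 0.2095, 0.0),
        y_n2o=zeros.copy(),
        y_co2=zeros.copy(),
        do_frac=do,
    )
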