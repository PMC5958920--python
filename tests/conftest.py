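import pytest

import mechanops as m


@pytest.fixture(scope="session")
def geometry():
    """Canonical calibrated device: 12 μm contraction, D_e = 30 μm."""
    return m.DeviceGeometry.standard(D_e=30.0)


@pytest.fixture(scope="session")
def acquisition():
    return m.AcquisitionConfig()


@pytest.fixture(scope="session")
def small_run(geometry, acquisition):
    """A 20-cell noise-free simulation pushed through the extraction chain,
    shared across tests that only read from it."""
    cfg = m.SimulationConfig(
        geometry=geometry, acquisition=acquisition, n_cells=20, noise_sd=0.0, seed=11
    )
    trace, truths = m.simulate_trace(cfg)
    records, rejects = m.extract_pulses(trace, geometry, acquisition)
    return cfg, trace, truths, records, rejects
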