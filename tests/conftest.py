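import pytest

from xlnrdyn import SimulationConfig, canonical_scenario


@pytest.fixture(scope="session")
def canonical():
    return canonical_scenario()


@pytest.fixture(scope="session")
def canonical_fb():
    return canonical_scenario(with_feedback=True)


@pytest.fixture(scope="session")
def fast_cfg():
    """Short horizon / coarse sampling, for tests that only need shapes."""
    return SimulationConfig(t_end=30.0, dt_out=0.1, rel_tol=1e-8, abs_tol=1e-10)
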