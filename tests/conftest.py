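import pytest
from hypothesis import settings

from guvscan import circuit, field, synth

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def model():
    """Default calibrated instrument model."""
    return circuit.default_model()


@pytest.fixture(scope="session")
def geometry():
    return field.SensorGeometry()


@pytest.fixture(scope="session")
def bundle():
    return synth.presets()


@pytest.fixture(scope="session")
def water_map(geometry):
    """Solved field map of the default geometry under uniform water."""
    return field.solve_potential(geometry, field.uniform_stack(78.4), resolution=24)
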