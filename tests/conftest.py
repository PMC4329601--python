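import pytest

from bsip import build_human, generate_synthetic_measurements, uniform_densities
from bsip.synthetic import FixtureParams


@pytest.fixture
def measurements():
    """A mildly asymmetric synthetic subject."""
    return generate_synthetic_measurements(FixtureParams(seed=42))


@pytest.fixture
def human(measurements):
    return build_human(measurements)


@pytest.fixture
def symmetric_human(measurements):
    return build_human(measurements, symmetric=True)


@pytest.fixture
def uniform_human(measurements):
    """Uniform density: results independent of the density constants."""
    return build_human(measurements, densities=uniform_densities())
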