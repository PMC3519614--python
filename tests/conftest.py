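"""Shared fixtures: default phantom anatomy and simulated frames.

Session scope keeps the expensive volumes (label rasterization, blurred
expectation images) computed once for the whole run.
"""

import numpy as np
import pytest

from datspect.synthetic_data import (AcquisitionSpec, KineticParams,
                                     PhantomSpec, expected_counts,
                                     make_brain_labels, simulate_acquisition,
                                     tracer_activity)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def kinetic_params():
    return KineticParams()


@pytest.fixture(scope="session")
def acquisition_spec():
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def labels(phantom_spec):
    return make_brain_labels(phantom_spec)


@pytest.fixture(scope="session")
def activity_4h(labels, kinetic_params, acquisition_spec):
    """Noiseless activity map at the 4 h scan time, physical decay included."""
    return tracer_activity(labels, kinetic_params, 4.0,
                           acquisition_spec.isotope_half_life_h)


@pytest.fixture(scope="session")
def expected_4h(activity_4h, acquisition_spec):
    """Blurred noise-free expected-count image at 4 h."""
    return expected_counts(activity_4h, acquisition_spec)


@pytest.fixture(scope="session")
def noisy_4h(activity_4h, acquisition_spec):
    """One seeded Poisson realization of the 4 h frame."""
    return simulate_acquisition(activity_4h, acquisition_spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
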