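"""Shared fixtures: the reference simulated groups and the (expensive) full study."""

import numpy as np
import pytest

from kadirect import ConcProfile, extract_features
from kadirect.pkmodels import PKParams2C
from kadirect.study import StudyConfig, run_validation, simulate_group

# the medium-ka reference group quoted throughout the validation table
GROUP_MEDIUM = PKParams2C(ka=0.603, k12=0.211, k21=0.176, k10=0.271)
# the slowest group (longest absorption, smallest terminal rate)
GROUP_SLOW = PKParams2C(ka=0.375, k12=0.133, k21=0.025, k10=0.100)
# the fast group used for the comparator spot-checks
GROUP_FAST_LR = PKParams2C(ka=1.098, k12=0.525, k21=0.176, k10=0.571)
GROUP_FAST_STM = PKParams2C(ka=1.098, k12=0.525, k21=0.176, k10=0.271)


@pytest.fixture(scope="session")
def medium_profile():
    return simulate_group(GROUP_MEDIUM, StudyConfig(horizon=96.0))


@pytest.fixture(scope="session")
def medium_features(medium_profile):
    return extract_features(medium_profile)


@pytest.fixture(scope="session")
def slow_profile():
    # horizon generous enough to cover the whole terminal phase
    return simulate_group(GROUP_SLOW, StudyConfig(horizon=96.0, beta_multiples=5.0))


@pytest.fixture(scope="session")
def study_report():
    """The full 39-group validation under the package defaults (with fits)."""
    return run_validation()


@pytest.fixture
def mono_exp_profile():
    """Densely sampled pure exponential decay, rate 0.1/h."""
    t = np.linspace(0.0, 200.0, 2001)
    return ConcProfile(times=t, conc=50.0 * np.exp(-0.1 * t))
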