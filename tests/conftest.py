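import numpy as np
import pytest

from rerand import TrialDesign, build_scenario_design, simulate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(20151105)


@pytest.fixture
def base_design():
    """The canonical enrolment mix: 100 patients once, 50 twice (200 obs)."""
    return TrialDesign(enrolment_strata=((100, 1), (50, 2)))


@pytest.fixture
def base_trial(rng):
    """One simulated base-scenario trial with a true effect of 0.4, ICC 0.5."""
    design, scenario = build_scenario_design("base", icc=0.5, beta=0.4)
    return simulate_trial(design, scenario, rng=rng)
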