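import numpy as np
import pytest

from gmisurv import PairedTrialData, Scenario, draw_paired_times


@pytest.fixture
def rng():
    return np.random.default_rng(20250)


@pytest.fixture
def small_trial():
    """3 patients, one censored second time."""
    return PairedTrialData([2.0, 4.0, 6.0], [4.0, 2.0, 6.0], [1, 1, 0])


@pytest.fixture
def uncensored_trial(rng):
    """A moderately sized fully observed trial from the simulator."""
    sc = Scenario(tau=0.2, shape_a=1.0, effect_e=1.0, censor_rate=0.0, n_patients=40)
    return draw_paired_times(sc, rng)
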