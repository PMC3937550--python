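import numpy as np
import pytest

from reprotime.estimation import Trial
from reprotime.synthetic import DesignSpec, SubjectParams, make_design, simulate_subject


@pytest.fixture(scope="session")
def default_design():
    return make_design(DesignSpec(seed=3))


@pytest.fixture(scope="session")
def noiseless_effect_trials(default_design):
    """One subject simulated without noise: kappa=0.03, eta P/N/E = 1.08/1.04/1."""
    params = SubjectParams(
        kappa=0.03, eta_v={"P": 1.08, "N": 1.04, "E": 1.0}, sigma_log=0.0
    )
    return simulate_subject(params, default_design, seed=0)


@pytest.fixture(scope="session")
def veridical_trials(default_design):
    """r = s exactly on every trial."""
    return [
        Trial(s=s, w=w, r=s, valence=v, subject_id="s01")
        for (v, s, w, _sid) in default_design
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
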