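import numpy as np
import pytest

import audcat as ac
from audcat import synthetic_data as synth


@pytest.fixture(scope="session")
def scale():
    return ac.FrequencyScale()


@pytest.fixture(scope="session")
def match_observer(scale):
    """Probability-matching observer with subjective categories matching the
    objective geometry (smoothing 0.1 octaves) at measured-scale noise."""
    cat_a, cat_b = ac.subjective_from_objective(scale, 0.1)
    return ac.ObserverModel(
        scale, cat_a, cat_b, {0.25: 0.25, 0.5: 0.5, 0.75: 0.75}, 0.02, "match"
    )


@pytest.fixture(scope="session")
def objective_map_observer(scale):
    return ac.ObserverModel.objective(scale, sigma_s=0.02, rule="map")


@pytest.fixture(scope="session")
def objective_match_observer(scale):
    return ac.ObserverModel.objective(scale, sigma_s=0.02, rule="match")


@pytest.fixture(scope="session")
def match_trials(match_observer):
    """One simulated subject: 3 sessions x 3 blocks x 150 trials."""
    design = synth.ExperimentDesign(n_sessions=3, trials_per_block=150, seed=101)
    trials = synth.generate_trial_sequence(design)
    return synth.simulate_observer(trials, match_observer, np.random.default_rng(202))
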