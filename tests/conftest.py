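import numpy as np
import pandas as pd
import pytest

import evoface as ef


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def category_means():
    return ef.default_category_means()


@pytest.fixture(scope="session")
def small_cohort():
    """Shared synthetic cohort: 12 participants, default dispersion."""
    spec = ef.CohortSpec(n_participants=12, between_subject_sd=0.15, seed=101)
    return ef.generate_cohort(spec)


@pytest.fixture(scope="session")
def recognition_setup():
    """Stimulus makers, perceivers, and simulated trials for recognition tests."""
    makers = ef.generate_cohort(ef.CohortSpec(n_participants=10, seed=201))
    perceivers = ef.generate_cohort(ef.CohortSpec(n_participants=8, seed=202))
    trials = ef.simulate_recognition(
        makers, perceivers, temperature=0.05, rng=np.random.default_rng(203)
    )
    return makers, perceivers, trials


def make_null_recognition(seed: int, n_perceivers: int = 8, trials_per: int = 80):
    """Dataset where preferred expressions carry no information: preferred
    sets, stimuli and responses are all mutually independent."""
    rng = np.random.default_rng(seed)
    pref = {
        f"p{j}": {e: ef.random_expression(rng, 0.5) for e in ef.EMOTIONS}
        for j in range(n_perceivers)
    }
    stim, rows = {}, []
    for j in range(n_perceivers):
        for t in range(trials_per):
            e = ef.EMOTIONS[t % 4]
            sid = f"s{j}_{t}"
            stim[sid] = ef.random_expression(rng, 0.5)
            resp = e if rng.random() < 0.7 else ef.EMOTIONS[rng.integers(4)]
            rows.append(
                {"perceiver_id": f"p{j}", "stimulus_id": sid,
                 "true_emotion": e, "response_emotion": resp}
            )
    return pd.DataFrame(rows), stim, pref, rng
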