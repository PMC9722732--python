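import copy

import numpy as np
import pytest

from cmcdetect.pipeline import PipelineConfig, run_pipeline
from cmcdetect.preprocess import epoch
from cmcdetect.synth import SimulationConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """10 task + 10 rest synthetic session used by preprocessing tests."""
    return generate_session(SimulationConfig(n_task_trials=10,
                                             n_rest_trials=10, seed=3))


@pytest.fixture(scope="session")
def _small_trials_master(small_session):
    return epoch(small_session)


@pytest.fixture
def small_trials(_small_trials_master):
    """Fresh (deep-copied) epoched TrialSet — screening mutates in place."""
    return copy.deepcopy(_small_trials_master)


@pytest.fixture(scope="session")
def pipeline_report():
    """One full default-condition pipeline run (20+20 trials) shared by tests."""
    return run_pipeline(PipelineConfig(seed=7), keep_data=True)


@pytest.fixture(scope="session")
def cohort():
    """Ten seeded default-condition sessions: the qualitative-trend cohort."""
    return [run_pipeline(PipelineConfig(seed=s)) for s in range(101, 111)]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
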