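import numpy as np
import pytest

from neuroloop.synthetic_data import (
    SyntheticConfig,
    make_recognition_schedule,
    make_templates,
    simulate_recognition_session,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A scaled-down design: 40 voxels, 3 runs of 16 trials."""
    return SyntheticConfig(n_voxels=40, n_runs_per_session=3, trials_per_run=16, seed=7)


@pytest.fixture(scope="session")
def templates(small_config):
    return make_templates(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, templates):
    schedules = [
        make_recognition_schedule(small_config, seed=100 + r)
        for r in range(small_config.n_runs_per_session)
    ]
    return simulate_recognition_session(
        templates, schedules, noise_sd=small_config.noise_sd, seed=42, session=1
    )


@pytest.fixture(scope="session")
def noisefree_dataset(small_config, templates):
    schedules = [
        make_recognition_schedule(small_config, seed=200 + r)
        for r in range(small_config.n_runs_per_session)
    ]
    return simulate_recognition_session(templates, schedules, noise_sd=0.0, seed=0, session=1)
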