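import numpy as np
import pytest

from doaeeg.synth import SimSpec, generate_dataset, make_trajectory, simulate_clean_eeg


@pytest.fixture(scope="session")
def small_spec():
    return SimSpec(n_subjects=2, duration_per_subject=24.0, seed=3)


@pytest.fixture(scope="session")
def small_subjects(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def clean_record(small_spec):
    traj = make_trajectory(small_spec, 0)
    return simulate_clean_eeg(small_spec, traj, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
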