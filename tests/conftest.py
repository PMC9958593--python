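import numpy as np
import pytest

from eegattn import evaluation, selection
from eegattn.pipeline import PipelineConfig, compute_feature_table
from eegattn.simulate import CohortConfig


@pytest.fixture(scope="session")
def cohort_config():
    """Reduced cohort (6 subjects, 30 s/task) keeping the default state
    profiles; small enough that the whole suite stays inside its budget."""
    return CohortConfig(n_subjects=6, n_sessions=2, task_duration_s=30.0, seed=11)


@pytest.fixture(scope="session")
def cohort_features(cohort_config):
    """Feature table extracted from the reduced synthetic cohort."""
    _, table = compute_feature_table(PipelineConfig(cohort=cohort_config))
    return table


@pytest.fixture(scope="session")
def cohort_xy(cohort_features):
    return selection.split_feature_frame(cohort_features)


@pytest.fixture(scope="session")
def cohort_split(cohort_xy):
    _, y = cohort_xy
    return evaluation.split_dataset(y, evaluation.SplitSpec(seed=0))


def make_planted_dataset(
    n_samples=400,
    n_groups=10,
    n_channels=10,
    informative=("F7",),
    noise_sd=0.05,
    seed=0,
):
    """Feature-major matrix where only the given groups carry the label."""
    rng = np.random.default_rng(seed)
    y = rng.integers(1, 5, size=n_samples)
    X = rng.standard_normal((n_samples, n_groups * n_channels))
    for gid in informative:
        cols = selection.feature_groups(n_channels)[gid]
        X[:, cols] = y[:, None] + noise_sd * rng.standard_normal(
            (n_samples, len(cols))
        )
    return X, y
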