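import numpy as np
import pytest

import mealpatterns as mp


@pytest.fixture(scope="session")
def composition():
    return mp.default_composition()


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-individual, 4-day cohort — small but structurally complete."""
    config = mp.CohortConfig(n_individuals=24, n_days=4, n_corrupted_days=2, seed=7)
    participants, diary, truth = mp.generate_cohort(config)
    return config, participants, diary, truth


@pytest.fixture(scope="session")
def small_series(small_cohort, composition):
    _, _, diary, _ = small_cohort
    clean, _ = mp.validate_days(diary)
    eos, items = mp.build_eos(clean, composition)
    return eos, items, mp.to_series(eos)


def euclidean_matrix(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))
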