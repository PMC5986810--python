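import numpy as np
import pytest

from sadnet import (
    PARADIGMS,
    PreprocessConfig,
    correlation_matrix,
    default_ground_truth,
    preprocess_set,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_spec():
    return default_ground_truth()


@pytest.fixture(scope="session")
def small_cohort(default_spec):
    """A 6-subject cohort: big enough for every stage, fast to analyze."""
    return simulate_cohort(default_spec, n_subjects_high=3, n_subjects_low=3, seed=42)


@pytest.fixture(scope="session")
def small_cohort_matrices(small_cohort):
    """Per-subject connectivity of the 6-subject cohort, default preprocessing."""
    prep = PreprocessConfig()
    by_paradigm = {p: [] for p in PARADIGMS}
    by_subject = {}
    for sub in small_cohort.subjects:
        by_subject[sub.subject_id] = {}
        for p in PARADIGMS:
            mat = correlation_matrix(preprocess_set(sub.timeseries[p], prep))
            by_paradigm[p].append(mat)
            by_subject[sub.subject_id][p] = mat
    return by_paradigm, by_subject


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_cliques():
    """Two disconnected 3-cliques with unit weights and their planted split."""
    w = np.zeros((6, 6))
    for block in (range(3), range(3, 6)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    return w, np.array([0, 0, 0, 1, 1, 1])
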