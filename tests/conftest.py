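import numpy as np
import pytest

from affwdi import cohort
from affwdi.cohort import BinarySpec, CohortConfig, ContinuousSpec


@pytest.fixture(scope="session")
def default_cohort():
    """One draw of the default 303-patient synthetic cohort."""
    return cohort.generate(cohort.default_config(seed=0))


@pytest.fixture
def separable_xy():
    """A linearly separable two-feature binary problem."""
    rng = np.random.default_rng(0)
    n = 60
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 2))
    X[:, 0] += 8.0 * y
    return X, y


def moderate_effect_config(seed: int) -> tuple[CohortConfig, set]:
    """A cohort where no single variable separates the groups on its own,
    so cross-validated accuracy genuinely rewards multi-feature subsets."""
    binary = tuple(BinarySpec(f"b{i}", 0.30, 0.62) for i in range(4)) + \
        (BinarySpec("noise_b", 0.5, 0.5),)
    cont = (ContinuousSpec("c0", 0.0, 1.0, 0.8, 1.0),
            ContinuousSpec("c1", 10.0, 2.0, 11.6, 2.0),
            ContinuousSpec("noise_c0", 0.0, 1.0, 0.0, 1.0),
            ContinuousSpec("noise_c1", 5.0, 1.0, 5.0, 1.0))
    cfg = CohortConfig(n_good=250, n_poor=150, binary=binary,
                       continuous=cont, seed=seed)
    return cfg, {"b0", "b1", "b2", "b3", "c0", "c1"}
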