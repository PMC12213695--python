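import numpy as np
import pandas as pd
import pytest

import vagicoda as vc


@pytest.fixture(scope="session")
def cohort113():
    """Default-condition synthetic cohort (113 subjects)."""
    return vc.generate_cohort(vc.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def cohort200():
    """Small cohort for regression-algebra checks."""
    return vc.generate_cohort(vc.CohortConfig(seed=2, n_subjects=200, include_ffq=False))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_composition():
    """Four 9-part compositions with distinct profiles."""
    data = np.array(
        [
            [10.5, 5.8, 19.6, 28.0, 12.1, 18.6, 4.8, 0.43, 0.18],
            [14.0, 5.0, 15.0, 30.0, 11.0, 19.0, 5.0, 0.50, 0.50],
            [8.0, 7.0, 25.0, 25.0, 13.0, 16.0, 5.0, 0.60, 0.40],
            [12.0, 6.0, 18.0, 26.0, 14.0, 18.0, 5.0, 0.70, 0.30],
        ]
    )
    return pd.DataFrame(data, columns=list(vc.PARTS))
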