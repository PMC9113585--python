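import numpy as np
import pandas as pd
import pytest

from paleoems.incidence import IncidenceStudy, study_from_arrays, stub_metadata


@pytest.fixture
def toy_study():
    """4 sites x 5 taxa, handwritten, no degenerate lines."""
    values = np.array(
        [
            [1, 1, 0, 0, 1],
            [1, 1, 1, 0, 0],
            [0, 1, 1, 1, 0],
            [0, 0, 1, 1, 1],
        ]
    )
    return study_from_arrays(values)


@pytest.fixture
def identity_study():
    return study_from_arrays(np.eye(2, dtype=int))


def make_study(values, **kwargs):
    return study_from_arrays(np.asarray(values), **kwargs)


@pytest.fixture
def make_study_factory():
    return make_study


def random_binary(rng, n, m, p=0.4):
    return (rng.random((n, m)) < p).astype(np.int8)
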