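import numpy as np
import pytest

from groupfa.datasets import split
from groupfa.gfa import GFA
from groupfa.simulate import generate, make_design


@pytest.fixture(scope="session")
def small_data():
    """Down-scaled synthetic set: N=120, D=(10, 7), same factor design."""
    design = make_design(120)
    data, truth = generate(design, D=(10, 7), tau=(5.0, 10.0), seed=7)
    return data, truth


@pytest.fixture(scope="session")
def small_fit(small_data):
    """A converged fit on the small set with over-specified K."""
    data, truth = small_data
    train, test = split(data, 0.8, seed=3)
    model = GFA(n_factors=8, random_state=0).fit(train)
    return model, train, test, truth


def pooled_corr(a, b):
    return float(np.corrcoef(np.ravel(a), np.ravel(b))[0, 1])
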