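import numpy as np
import pytest

from neofit.cross_reactivity import CrossReactModel, PositionProfile, SubstitutionMatrix
from neofit.data_model import AA_ALPHABET, EpitopeSet
from neofit.synthetic_data import SimConfig, default_true_matrix, default_true_profile

AA_IDX = {a: i for i, a in enumerate(AA_ALPHABET)}


@pytest.fixture(scope="session")
def true_profile():
    return default_true_profile(9)


@pytest.fixture(scope="session")
def true_matrix():
    return default_true_matrix(7)


@pytest.fixture(scope="session")
def xreact_model(true_profile, true_matrix):
    return CrossReactModel(matrix=true_matrix, profile=true_profile)


def make_toy_model(length=3, weights=(0.5, 1.0, 1.5), cells=(("A", "G", 2.0),)):
    """Hand-specified model for arithmetic checks: zero matrix plus named cells."""
    entries = np.zeros((20, 20))
    support = np.zeros((20, 20), dtype=int)
    for a, b, v in cells:
        entries[AA_IDX[a], AA_IDX[b]] = v
        support[AA_IDX[a], AA_IDX[b]] = 1
    return CrossReactModel(
        matrix=SubstitutionMatrix(entries=entries, support=support),
        profile=PositionProfile(weights=np.array(weights, dtype=float), length=length),
    )


@pytest.fixture
def toy_model():
    return make_toy_model()


@pytest.fixture
def toy_epitopes():
    return EpitopeSet(entries=[("e1", "NLVPMVATV"), ("e2", "GILGFVFTL"), ("e3", "SLYNTVATL")])


@pytest.fixture
def sim_config():
    return SimConfig(seed=11, n_patients=3)
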