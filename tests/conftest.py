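import numpy as np
import pytest

from dynoa import builtin_model, make_fixture, transcribe
from dynoa.oa_engine import default_contract


@pytest.fixture(scope="session")
def pinene():
    return builtin_model("alpha_pinene")


@pytest.fixture(scope="session")
def hiv():
    return builtin_model("hiv_proteinase")


@pytest.fixture(scope="session")
def pinene_clean():
    return make_fixture("pinene_clean", seed=1)


@pytest.fixture(scope="session")
def pinene_noisy():
    return make_fixture("pinene_noisy", seed=7)


@pytest.fixture(scope="session")
def hiv_small():
    return make_fixture("hiv_small", seed=3)


@pytest.fixture(scope="session")
def contract():
    return default_contract()


@pytest.fixture(scope="session")
def pinene_nlp(pinene_clean):
    model, obs, ds, _ = pinene_clean
    return transcribe(model, ds, 5, 3, obs=obs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
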