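import numpy as np
import pytest

from claderates.codon_model import CodonModelMatrices, Mg94Params
from claderates.genetic_codes import get_genetic_code


@pytest.fixture(scope="session")
def standard_code():
    return get_genetic_code("standard")


@pytest.fixture(scope="session")
def mito_code():
    return get_genetic_code("vertebrate_mitochondrial")


def random_mg94(seed: int, omega: float = 0.3) -> Mg94Params:
    rng = np.random.default_rng(seed)
    ex = rng.uniform(0.3, 4.0, 6)
    ex[5] = 1.0
    pi = rng.dirichlet(np.full(4, 8.0), size=3)
    return Mg94Params(ex, pi, omega)


@pytest.fixture(scope="session")
def random_params():
    return random_mg94(17)


@pytest.fixture(scope="session")
def standard_mats(random_params, standard_code):
    return CodonModelMatrices(random_params, standard_code)
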