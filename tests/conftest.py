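import numpy as np
import pytest
from hypothesis import settings

from spacegt import Seed, parse_seed

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

# the published palindromic seed of weight 31 and its 26-position base
S1_BASE = "11101110010101001101001111"
S1 = "111011100101010011010011111110010110010101001110111"


@pytest.fixture(scope="session")
def s1_seed() -> Seed:
    return parse_seed(S1)


@pytest.fixture(scope="session")
def s1_base_seed() -> Seed:
    return parse_seed(S1_BASE)


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
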