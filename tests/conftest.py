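import numpy as np
import pytest

from triple_entropy import EmissionModel, RnaSequence, solve_rule_probabilities

ALPHABET = list("ACGU")


@pytest.fixture(scope="session")
def em():
    return EmissionModel.default()


@pytest.fixture(scope="session")
def params(em):
    return solve_rule_probabilities(em)


@pytest.fixture(scope="session")
def oracle_panel():
    """200 random sequences with n in [7, 12], the brute-force test panel."""
    rng = np.random.default_rng(12345)
    panel = []
    for k in range(200):
        n = int(rng.integers(7, 13))
        panel.append(
            RnaSequence(f"panel{k}", "".join(rng.choice(ALPHABET, size=n)))
        )
    return panel


def random_sequence(rng, n, identifier="rand"):
    return RnaSequence(identifier, "".join(rng.choice(ALPHABET, size=n)))
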