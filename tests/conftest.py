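import numpy as np
import pytest

from tfdissect.pwm import PositionWeightMatrix, encode
from tfdissect.datasets import CONSENSUS


def pwm_from_consensus(seq: str, weight: float = 20.0,
                       pseudo: float = 0.25) -> PositionWeightMatrix:
    """Sharp PWM concentrated on a consensus sequence."""
    counts = np.zeros((len(seq), 4))
    counts[np.arange(len(seq)), encode(seq)] = weight
    return PositionWeightMatrix.from_counts(counts, pseudocount=pseudo)


@pytest.fixture(scope="session")
def consensus() -> str:
    return CONSENSUS


@pytest.fixture(scope="session")
def consensus_pwm(consensus) -> PositionWeightMatrix:
    return pwm_from_consensus(consensus)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_pwm(rng, width: int, conc: float = 2.0) -> PositionWeightMatrix:
    return PositionWeightMatrix(rng.dirichlet(np.full(4, conc), size=width))
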