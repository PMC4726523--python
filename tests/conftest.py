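import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from irdyn.evolution import ModelParams
from irdyn.fitness import PayoffParams
from irdyn.norms import named_norm
from irdyn.strategies import ErrorRates

#: Baseline study conditions: b=5, c=1, alpha=chi=0.01, epsilon=0.08, beta=1.
BASE_ERRORS = ErrorRates(alpha=0.01, epsilon=0.08, chi=0.01)
BASE_PAYOFF = PayoffParams(b=5.0, c=1.0)


def base_params(Z: int, norm_name: str = "SJ", beta: float = 1.0) -> ModelParams:
    return ModelParams(
        Z=Z, norm=named_norm(norm_name), payoff=BASE_PAYOFF, errors=BASE_ERRORS, beta=beta
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160125)
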