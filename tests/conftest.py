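import numpy as np
import pytest
from hypothesis import settings

from slimechoice import ModelParams

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def japan() -> ModelParams:
    """Best-fit rates of the Japanese strain (pitchfork at M3 = 4.2)."""
    return ModelParams(k=2.5, d=1.0, T=1.5, n=2, M=4.0)


def random_params(rng: np.random.Generator, M_factor: float | None = None,
                  n: int = 2) -> ModelParams:
    """A random valid parameter draw; mass relative to M3 when requested."""
    k = rng.uniform(0.3, 4.0)
    d = rng.uniform(0.3, 3.0)
    T = rng.uniform(0.3, 3.0)
    M3 = 2.0 * T * (k + d) / k
    M = rng.uniform(0.2, 2.0) * M3 if M_factor is None else M_factor * M3
    return ModelParams(k=k, d=d, T=T, n=n, M=M)
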