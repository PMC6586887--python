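import numpy as np
import pytest

from truel import ALL_STRATEGIES, Marksmanship, StrategyProfile


def random_marksmanship(rng: np.random.Generator) -> Marksmanship:
    """A random valid triple: sorted uniforms with the strongest player nonzero."""
    while True:
        a, b, c = np.sort(rng.random(3))
        if c > 1e-9:
            return Marksmanship(float(a), float(b), float(c))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture(params=[s.value for s in ALL_STRATEGIES])
def any_profile(request) -> StrategyProfile:
    return StrategyProfile(request.param)
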