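import numpy as np
import pytest

from soflr import ActivationMatrix, OverlapCurve

# Mean overlap-decay curve of the six cadmium-transformed isolates
# (induced direction), k = 1..6.
CD_INDUCED_CURVE = (1673.0, 850.0, 574.0, 433.0, 346.0, 285.0)


@pytest.fixture
def cd_curve() -> OverlapCurve:
    return OverlapCurve(y=np.asarray(CD_INDUCED_CURVE))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def random_activation(
    rng: np.random.Generator, n_probes: int, n_isolates: int, density: float = 0.4
) -> ActivationMatrix:
    calls = rng.random((n_probes, n_isolates)) < density
    return ActivationMatrix(
        probe_ids=tuple(f"p{i}" for i in range(n_probes)),
        isolate_ids=tuple(f"iso{j}" for j in range(n_isolates)),
        calls=calls,
    )
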