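from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dstcall.evidence import Evidence

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_evidences(rng: np.random.Generator, n: int, alpha0: float = 1.0):
    """n random triples drawn from a Dirichlet over the 2-simplex."""
    draws = rng.dirichlet([alpha0, alpha0, alpha0], size=n)
    return [Evidence(a, b, t) for a, b, t in draws]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220402)


@pytest.fixture
def grid_evidences() -> list[Evidence]:
    """All evidence triples on the 0.1 mass grid (66 triples)."""
    out = []
    for ai in range(11):
        for bi in range(11 - ai):
            out.append(Evidence(ai / 10.0, bi / 10.0, (10 - ai - bi) / 10.0))
    return out
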