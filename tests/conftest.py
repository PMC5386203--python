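"""Shared fixtures: session-scoped network ensembles reused across the suite.

The study conditions are the model's canonical ones (m = 3, beta = 2/3,
gamma = 2.5) at n = 10^3 for ensembles and n = 10^4 for gap-autocorrelation
and clustering-spectrum checks.  Seeds are fixed so every run is identical.
"""

from __future__ import annotations

import numpy as np
import pytest

from gpanet.simulator import GPANetwork, ModelParams, grow_network

LAMBDAS = (0.1, 1.0, 10.0)


def _grow(n, lam, seed, **kw):
    return grow_network(ModelParams(n=n, m=3, beta=2.0 / 3.0, lambda_schedule=lam,
                                    seed=seed, **kw))


@pytest.fixture(scope="session")
def small_ensembles() -> dict[float, list[GPANetwork]]:
    """10 replicate networks (n = 10^3) per Lambda in {0.1, 1, 10}."""
    return {
        lam: [_grow(1000, lam, 1000 * (j + 1) + i) for i in range(10)]
        for j, lam in enumerate(LAMBDAS)
    }


@pytest.fixture(scope="session")
def angle_ensembles() -> dict[float, list[np.ndarray]]:
    """Angular coordinates of 100 replicate networks (n = 10^3) per Lambda."""
    return {
        lam: [_grow(1000, lam, 20_000 * (j + 1) + i).angles for i in range(100)]
        for j, lam in enumerate(LAMBDAS)
    }


@pytest.fixture(scope="session")
def big_networks() -> dict[float, list[GPANetwork]]:
    """Two n = 10^4 networks each at Lambda = 0.1 and Lambda = 10."""
    return {lam: [_grow(10_000, lam, int(90_000 + 10 * lam + i)) for i in range(2)]
            for lam in (0.1, 10.0)}
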