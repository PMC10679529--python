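import math

import numpy as np
import pytest

from tremorloop.oscillators import SimulationConfig


def apen_bruteforce(u, m, r):
    """Independent brute-force approximate entropy.

    Direct transcription of the defining equations: for embedding length
    k, form all N-k+1 template vectors, count matches under the Chebyshev
    distance (self-matches included), and average the log relative counts.
    Quadratic loops on purpose — this is the oracle, not the implementation.
    """
    u = list(map(float, u))
    N = len(u)

    def phi(k):
        n_vec = N - k + 1
        vecs = [u[i : i + k] for i in range(n_vec)]
        total = 0.0
        for vi in vecs:
            count = 0
            for vj in vecs:
                d = max(abs(a - b) for a, b in zip(vi, vj))
                if d <= r:
                    count += 1
            total += math.log(count / n_vec)
        return total / n_vec

    return phi(m) - phi(m + 1)


@pytest.fixture
def short_sim():
    """A cheap integration window for unit tests."""
    return SimulationConfig(t_end=20.0, dt_out=0.001, transient_discard=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
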