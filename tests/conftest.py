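import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from porecall import EventSequence, ScalingParams, simulate_pore_model
from porecall.transitions import TransitionModel


@pytest.fixture(scope="session")
def k2_model():
    return simulate_pore_model(11, 2, "k2")


@pytest.fixture(scope="session")
def k6_model():
    return simulate_pore_model(11, 6, "template")


@pytest.fixture(scope="session")
def trans_k2():
    return TransitionModel(0.1, 0.3, K=2)


@pytest.fixture
def neutral():
    return ScalingParams()


def random_events(seed: int, n: int) -> EventSequence:
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(0.01, 0.02, n)
    starts = np.concatenate([[0.0], np.cumsum(lengths[:-1])])
    return EventSequence(starts, lengths, rng.uniform(50, 90, n), rng.uniform(0.8, 3.0, n))


def enumerate_paths(log_emissions: np.ndarray, trans: TransitionModel):
    """Brute-force oracle: sum / argmax over every state path.

    Returns (total log-likelihood, best joint log-prob, best path), with the
    best path being the lexicographically smallest among ties (matching the
    smallest-predecessor tie-break of the DP).
    """
    n, S = log_emissions.shape
    with np.errstate(divide="ignore"):
        logT = np.log(np.asarray(trans.trans_csr.todense()))
    paths = np.indices((S,) * n).reshape(n, -1)  # (n, S**n), axis0 varies slowest
    lp = -np.log(S) + log_emissions[0, paths[0]]
    for t in range(1, n):
        lp = lp + logT[paths[t - 1], paths[t]] + log_emissions[t, paths[t]]
    m = lp.max()
    total = float(np.log(np.exp(lp - m).sum()) + m)
    best = int(np.argmax(lp))  # first max = lexicographically smallest path
    return total, float(lp[best]), tuple(int(paths[t, best]) for t in range(n))
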