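import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from cryptoswarm import SearchParams, parse_puzzle, run_search
from cryptoswarm.puzzle import DONALD_GERALD_ROBERT

#: Known solution of the classic instance, verified independently in tests.
DONALD_SOLUTION = dict(D=5, O=2, N=6, A=4, L=8, G=1, E=9, R=7, B=3, T=0)

#: 4-letter puzzle with exactly one solution among its 5040 states
#: (uniqueness asserted against the itertools oracle in test_puzzle).
UNIQUE4 = "AA+BA=ACD"


@pytest.fixture(scope="session")
def donald():
    return parse_puzzle(DONALD_GERALD_ROBERT)


@pytest.fixture(scope="session")
def small3():
    """3-letter puzzle (720 states, many solutions) for fast dynamics tests."""
    return parse_puzzle("A+B=C")


@pytest.fixture(scope="session")
def unique4():
    return parse_puzzle(UNIQUE4)


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels(small3):
    """Compile the numba kernels once up front so timings inside tests are
    not dominated by JIT."""
    run_search(small3, SearchParams(N=3, p=0.5, K=2, seed=0, max_trials=10_000))
    run_search(
        small3,
        SearchParams(N=2, p=0.0, K=0, seed=0, move_kind="global", max_trials=10_000),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
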