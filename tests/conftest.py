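import numpy as np
import pytest

from scmetal.simulate import SimParams, simulate_run
from scmetal.trace_io import RunConfig


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def default_run():
    """One default synthetic run (seed 11), shared read-only across tests."""
    params = SimParams(seed=11)
    trace, events, truths = simulate_run(params)
    return params, trace, events, truths


def brute_force_peak(y: np.ndarray, thr: float, rule: str):
    """Independent boundary-search oracle: enumerate every candidate boundary.

    Returns (i_left, i_right, i_apex, integral, edge_truncated) or None.
    Deliberately exhaustive: collects *all* indices that qualify as a left or
    right boundary under the rule and picks the one nearest the core region.
    """
    y = np.asarray(y, dtype=float)
    if not np.any(y > thr):
        return None
    i_apex = int(np.argmax(y))
    # core: contiguous run above thr containing the apex
    lo = i_apex
    while lo > 0 and y[lo - 1] > thr:
        lo -= 1
    hi = i_apex
    while hi < len(y) - 1 and y[hi + 1] > thr:
        hi += 1

    def qualifies(j):
        if y[j] > thr:
            return False
        if rule == "first_at_or_below":
            return True
        left = j == 0 or y[j] <= y[j - 1]
        right = j == len(y) - 1 or y[j] <= y[j + 1]
        return left and right

    lefts = [j for j in range(0, lo) if qualifies(j)]
    rights = [j for j in range(hi + 1, len(y)) if qualifies(j)]
    truncated = False
    if lefts:
        i_left = max(lefts)
    else:
        i_left, truncated = 0, True
    if rights:
        i_right = min(rights)
    else:
        i_right, truncated = len(y) - 1, True
    return i_left, i_right, i_apex, float(y[i_left : i_right + 1].sum()), truncated
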