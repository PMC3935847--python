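import numpy as np
import pytest

from ctrlcascade import DirectedGraph, toy_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path3():
    return toy_fixture("path3")


@pytest.fixture
def cycle3():
    return toy_fixture("cycle3")


@pytest.fixture
def matching_demo():
    return toy_fixture("matching_demo")


@pytest.fixture
def reroute_graph():
    """Two sources feed a hub with a direct and a detour route to a second
    hub serving two sinks; removing the direct edge reroutes all traffic
    onto the detour and overloads it — a minimal propagating cascade."""
    return DirectedGraph(
        7, ((0, 2), (1, 2), (2, 3), (2, 4), (4, 3), (3, 5), (3, 6))
    )
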