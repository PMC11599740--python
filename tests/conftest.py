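import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import qualdyn as q
from qualdyn import case_study


@pytest.fixture(scope="session")
def two_node_net():
    """a activates b, b inhibits a — the classic homeostatic pair."""
    return q.build_network(
        [("a", 1), ("b", 1)], [("a", "b", "+", 1), ("b", "a", "-", 1)]
    )


@pytest.fixture(scope="session")
def two_node_model(two_node_net):
    """Parameters realizing the 4-state oscillation (0,0)→(1,0)→(1,1)→(0,1)."""
    params = q.ParameterSet(
        {
            "a": {frozenset(): 0, frozenset({"b"}): 1},
            "b": {frozenset(): 0, frozenset({"a"}): 1},
        }
    )
    return q.ModelInstance(two_node_net, params)


@pytest.fixture(scope="session")
def two_node_graph(two_node_model):
    return q.build_state_graph(two_node_model)


@pytest.fixture(scope="session")
def hif1_model():
    return case_study.load_canonical_model()


@pytest.fixture(scope="session")
def hif1_graph(hif1_model):
    return q.build_state_graph(hif1_model)


@pytest.fixture(scope="session")
def hif1_fixtures():
    return case_study.load_fixtures()
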