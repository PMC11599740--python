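"""Asynchronous unitary dynamics: state graphs, fixed points, attractors.

A model instance pairs a network with a complete logical-parameter table.
Its state graph enumerates every qualitative state; from a state, each entity
whose current level differs from its target K moves one unit toward it
(unitary asynchronous semantics), each such move giving one transition.
A state with no outgoing transition is a fixed point (deadlock); attractors
are the terminal strongly connected components of the graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import networkx as nx

from .network import (
    NetworkValidationError,
    ParameterSet,
    RegulatoryNetwork,
    resources,
    state_count,
)

__all__ = [
    "ModelInstance",
    "StateGraph",
    "Attractor",
    "StateSpaceTooLargeError",
    "target_level",
    "successors",
    "build_state_graph",
    "fixed_points",
    "attractors",
    "is_reachable",
]

State = Tuple[int, ...]

#: Refuse to enumerate state spaces beyond this size by default.
DEFAULT_STATE_CAP = 10**6


class StateSpaceTooLargeError(NetworkValidationError):
    pass


@dataclass(frozen=True)
class ModelInstance:
    """A network together with a complete parameter set."""

    network: RegulatoryNetwork
    parameters: ParameterSet

    def __post_init__(self) -> None:
        self.parameters.check_complete(self.network)


def target_level(model: ModelInstance, state: Sequence[int], entity: str) -> int:
    """The level entity is attracted toward: K(entity, resources(state))."""
    res = resources(model.network, state, entity)
    return model.parameters.k(entity, res)


def successors(model: ModelInstance, state: Sequence[int]) -> Set[State]:
    """Asynchronous unitary successors of ``state``.

    One transition per entity whose level differs from its target, moving
    that entity one unit toward the target.  Empty set iff fixed point.
    """
    net = model.network
    state = net.check_state(state)
    out: Set[State] = set()
    for i, name in enumerate(net.entity_names):
        k = target_level(model, state, name)
        if k > state[i]:
            out.add(state[:i] + (state[i] + 1,) + state[i + 1 :])
        elif k < state[i]:
            out.add(state[:i] + (state[i] - 1,) + state[i + 1 :])
    return out


class StateGraph:
    """Exhaustive asynchronous state transition graph of a model.

    ``states`` is the full lexicographic enumeration; ``graph`` a
    :class:`networkx.DiGraph` over state tuples.  Fixed points are kept as
    plain deadlock nodes here; CTL evaluation totalizes the relation with
    implicit self-loops (see :mod:`qualdyn.ctl`).
    """

    def __init__(self, model: ModelInstance, graph: nx.DiGraph, states: List[State]):
        self.model = model
        self.network = model.network
        self.graph = graph
        self.states = states
        self._state_set = set(states)

    @property
    def transitions(self) -> Set[Tuple[State, State]]:
        return set(self.graph.edges())

    def __contains__(self, state: State) -> bool:
        return tuple(state) in self._state_set

    def check_state(self, state: Sequence[int]) -> State:
        state = tuple(state)
        if state not in self._state_set:
            raise NetworkValidationError(f"state {state} not in state graph")
        return state

    def successors_of(self, state: State) -> List[State]:
        return sorted(self.graph.successors(self.check_state(state)))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"StateGraph({len(self.states)} states, "
            f"{self.graph.number_of_edges()} transitions)"
        )


def build_state_graph(model: ModelInstance, cap: int = DEFAULT_STATE_CAP) -> StateGraph:
    """Enumerate all states and all asynchronous unitary transitions.

    States are generated in lexicographic order over the network's entity
    order, so the graph (and every export derived from it) is deterministic.
    Refuses state spaces larger than ``cap``.
    """
    net = model.network
    z = state_count(net)
    if z > cap:
        raise StateSpaceTooLargeError(
            f"state space has {z} states, exceeding the cap of {cap}; "
            "raise `cap` explicitly to proceed"
        )
    ranges = [range(m + 1) for m in net.max_levels]
    states: List[State] = [tuple(s) for s in itertools.product(*ranges)]
    g = nx.DiGraph()
    g.add_nodes_from(states)
    for s in states:
        for t in sorted(successors(model, s)):
            g.add_edge(s, t)
    return StateGraph(model, g, states)


def fixed_points(model: ModelInstance, cap: int = DEFAULT_STATE_CAP) -> List[State]:
    """All deadlock states (no successor), in lexicographic order."""
    net = model.network
    z = state_count(net)
    if z > cap:
        raise StateSpaceTooLargeError(
            f"state space has {z} states, exceeding the cap of {cap}"
        )
    ranges = [range(m + 1) for m in net.max_levels]
    out = []
    for s in itertools.product(*ranges):
        s = tuple(s)
        if not successors(model, s):
            out.append(s)
    return out


@dataclass(frozen=True)
class Attractor:
    """A terminal SCC of the state graph.

    ``kind`` is ``"fixed_point"`` for a singleton with no outgoing
    transition, ``"cyclic"`` otherwise.
    """

    kind: str
    states: FrozenSet[State]

    def __contains__(self, state: State) -> bool:
        return tuple(state) in self.states


def attractors(graph: StateGraph) -> List[Attractor]:
    """All terminal SCCs, deterministically ordered by smallest member state."""
    cond = nx.condensation(graph.graph)
    out: List[Attractor] = []
    for node in cond.nodes:
        if cond.out_degree(node) == 0:
            members = frozenset(cond.nodes[node]["members"])
            if len(members) == 1:
                (s,) = members
                kind = "fixed_point" if graph.graph.out_degree(s) == 0 else "cyclic"
            else:
                kind = "cyclic"
            out.append(Attractor(kind, members))
    out.sort(key=lambda a: min(a.states))
    return out


def is_reachable(
    graph: StateGraph, src: Sequence[int], dst: Iterable[Sequence[int]] | Sequence[int]
) -> bool:
    """True iff a directed path exists from ``src`` to ``dst`` (state or set)."""
    src = graph.check_state(src)
    if dst and isinstance(next(iter(dst)), int):
        targets = {graph.check_state(dst)}  # a single state
    else:
        targets = {graph.check_state(d) for d in dst}
    if src in targets:
        return True
    reachable = nx.descendants(graph.graph, src)
    return bool(reachable & targets)
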