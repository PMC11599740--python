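"""Betweenness-centrality analysis of state graphs.

State graphs of realistic models are too large to read by eye, so important
qualitative states are ranked by directed betweenness centrality

    BC(s) = Σ_{u ≠ v ≠ s}  σ_{u,v}(s) / σ_{u,v}

(σ counted over shortest directed paths, endpoints excluded, pairs with no
path contributing zero, no normalization — rankings are invariant to the
constant factor anyway).  On top of the ranking the module extracts the
maximal-centrality cycle, maximal-centrality shortest paths between regions,
and bifurcation states from which distinct attractors remain reachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .dynamics import Attractor, StateGraph

__all__ = [
    "CentralityMap",
    "TrajectoryReport",
    "betweenness_centrality",
    "rank_states",
    "max_centrality_cycle",
    "bifurcation_states",
    "max_centrality_path",
    "recovery_attractors",
    "classify_states",
]

State = Tuple[int, ...]
CentralityMap = Dict[State, float]


def betweenness_centrality(graph: StateGraph) -> CentralityMap:
    """Unnormalized directed betweenness centrality of every state."""
    return nx.betweenness_centrality(graph.graph, normalized=False)


def rank_states(cmap: CentralityMap) -> List[State]:
    """States in descending centrality, lexicographic tie-break (stable)."""
    return sorted(cmap, key=lambda s: (-cmap[s], s))


@dataclass
class TrajectoryReport:
    """An extracted path or cycle with per-state centrality annotations.

    ``classification`` labels each state ``toward_deadlock``,
    ``toward_recovery`` or ``bifurcation`` when attractor context was given
    (states inside an attractor are labeled by that attractor's role).
    """

    kind: str  # "path" | "cycle"
    states: List[State]
    centrality: List[float]
    classification: Dict[State, str] = field(default_factory=dict)

    @property
    def mean_centrality(self) -> float:
        return sum(self.centrality) / len(self.centrality) if self.centrality else 0.0

    def validate_edges(self, graph: StateGraph) -> None:
        pairs = list(zip(self.states, self.states[1:]))
        if self.kind == "cycle" and self.states:
            pairs.append((self.states[-1], self.states[0]))
        for a, b in pairs:
            if not graph.graph.has_edge(a, b):
                raise ValueError(f"trajectory edge {a} -> {b} not in graph")


def _score(values: Sequence[float], criterion: str) -> float:
    if not values:
        return 0.0
    if criterion == "mean":
        return sum(values) / len(values)
    if criterion == "min":
        return min(values)
    if criterion == "sum":
        return sum(values)
    raise ValueError(f"unknown criterion {criterion!r}")


def max_centrality_cycle(
    graph: StateGraph,
    cmap: Optional[CentralityMap] = None,
    search_cap: int = 100_000,
    criterion: str = "mean",
) -> TrajectoryReport:
    """The simple cycle maximizing the centrality of its states.

    Simple cycles are enumerated (deterministically, up to ``search_cap``)
    and scored by the ``criterion`` aggregate of member centralities; ties
    are broken toward longer cycles, then by lexicographically smallest
    rotation.  Self-loops are ignored.  Raises on acyclic graphs.
    """
    cmap = cmap if cmap is not None else betweenness_centrality(graph)
    best = None
    n_seen = 0
    for cyc in nx.simple_cycles(graph.graph):
        if len(cyc) < 2:
            continue
        n_seen += 1
        # canonical rotation: start at smallest state
        i = cyc.index(min(cyc))
        cyc = cyc[i:] + cyc[:i]
        key = (_score([cmap[s] for s in cyc], criterion), len(cyc), tuple(cyc))
        if best is None or (key[0], key[1]) > (best[0], best[1]) or (
            (key[0], key[1]) == (best[0], best[1]) and key[2] < best[2]
        ):
            best = key
        if n_seen >= search_cap:
            break
    if best is None:
        raise ValueError("graph has no cycle of length >= 2 within the search cap")
    states = list(best[2])
    return TrajectoryReport(
        kind="cycle", states=states, centrality=[cmap[s] for s in states]
    )


def bifurcation_states(graph: StateGraph, atts: Sequence[Attractor]) -> List[State]:
    """Non-attractor states with two successors leading to different futures.

    A state qualifies when at least two of its successors have *different*
    sets of reachable attractors — the system's fate genuinely branches
    there.  Deterministic (lexicographic) order.
    """
    att_states: Set[State] = set().union(*(a.states for a in atts)) if atts else set()
    out = []
    for s in graph.states:
        if s in att_states:
            continue
        succ = list(graph.graph.successors(s))
        if len(succ) < 2:
            continue
        reach_sets = set()
        for t in succ:
            r = nx.descendants(graph.graph, t) | {t}
            reach_sets.add(frozenset(i for i, a in enumerate(atts) if a.states & r))
        if len(reach_sets) > 1:
            out.append(s)
    return out


def recovery_attractors(
    atts: Sequence[Attractor], labels: Dict[int, int]
) -> List[Attractor]:
    """Attractors all of whose states carry the given coordinate labels.

    ``labels`` maps entity index -> required level (e.g. the homeostatic
    region constraints); an attractor is a *recovery* attractor when every
    member state matches on every constrained coordinate.
    """
    out = []
    for a in atts:
        if all(all(s[i] == lvl for i, lvl in labels.items()) for s in a.states):
            out.append(a)
    return out


def classify_states(
    graph: StateGraph,
    atts: Sequence[Attractor],
    recovery: Sequence[Attractor],
    states: Iterable[State],
) -> Dict[State, str]:
    """Label states by which kind of attractor remains reachable.

    ``toward_recovery`` when only recovery attractors are reachable,
    ``toward_deadlock`` when only non-recovery ones are, ``bifurcation``
    when both kinds remain reachable.
    """
    recovery_ids = {id(a) for a in recovery}
    out: Dict[State, str] = {}
    for s in states:
        s = tuple(s)
        reach = nx.descendants(graph.graph, s) | {s}
        kinds = set()
        for a in atts:
            if a.states & reach:
                kinds.add("recovery" if id(a) in recovery_ids else "deadlock")
        if kinds == {"recovery"}:
            out[s] = "toward_recovery"
        elif kinds == {"deadlock"}:
            out[s] = "toward_deadlock"
        else:
            out[s] = "bifurcation"
    return out


def max_centrality_path(
    graph: StateGraph,
    cmap: Optional[CentralityMap],
    src: Sequence[int],
    dst: Iterable[Sequence[int]],
    atts: Optional[Sequence[Attractor]] = None,
    recovery: Optional[Sequence[Attractor]] = None,
) -> TrajectoryReport:
    """Among shortest src→dst paths, the one with maximal mean centrality.

    ``dst`` is a set of target states; only paths of minimal length (to the
    nearest target) compete.  Intermediate states (endpoints excluded) are
    scored; ties break toward the lexicographically smallest path.  With
    attractor context given, each state is classified via
    :func:`classify_states`.
    """
    cmap = cmap if cmap is not None else betweenness_centrality(graph)
    src = graph.check_state(src)
    targets = [graph.check_state(d) for d in dst]
    best_len = None
    lengths = {}
    for t in targets:
        try:
            lengths[t] = nx.shortest_path_length(graph.graph, src, t)
        except nx.NetworkXNoPath:
            continue
    if not lengths:
        raise ValueError(f"no target reachable from {src}")
    best_len = min(lengths.values())
    candidates = []
    for t, l in lengths.items():
        if l == best_len:
            candidates.extend(nx.all_shortest_paths(graph.graph, src, t))
    def path_key(p):
        inner = [cmap[s] for s in p[1:-1]]
        return (-_score(inner, "mean"), tuple(p))
    best_path = min(candidates, key=path_key)
    report = TrajectoryReport(
        kind="path",
        states=list(best_path),
        centrality=[cmap[s] for s in best_path],
    )
    if atts is not None:
        report.classification = classify_states(
            graph, atts, recovery or [], best_path
        )
    report.validate_edges(graph)
    return report
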