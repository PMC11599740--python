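"""CTL-constrained identification of logical parameter sets.

Given a network and a CTL specification encoding observed behaviors, this
module enumerates the complete logical-parameter tables whose asynchronous
state graph satisfies the specification — the classical model-checking route
to parameter identification in the Thomas framework.

The raw search space is the product over entities of all K tables
(2^(2^|regulators|) per Boolean entity), which is astronomically large for
realistic networks, so the search is pruned by *steady-state propagation*:
every ``AG(c)`` subformula whose conjunction of atoms ``c`` must be realized
somewhere forces, for each entity named in ``c`` whose resource set is the
same in every completion of ``c``, one K entry to the level ``c`` assigns.
Surviving candidates are verified exactly with the CTL checker.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .ctl import And, Atom, CtlFormula, Temporal, holds
from .dynamics import ModelInstance, StateGraph, attractors, build_state_graph, fixed_points
from .network import ParameterSet, RegulatoryNetwork, _subsets, validate_parameter_set

__all__ = [
    "EnumerationOptions",
    "ModelCatalog",
    "SelectionCriteria",
    "EnumerationCapExceeded",
    "NoModelMeetsCriteria",
    "forced_entries",
    "enumerate_parameter_sets",
    "satisfies_spec",
    "parameter_table",
    "select_model",
]

State = Tuple[int, ...]


@dataclass
class EnumerationOptions:
    """Search configuration.

    ``snoussi``/``observability`` restrict candidate tables structurally;
    ``holds_mode`` is the CTL verdict mode (``all_states`` is the parameter-
    identification convention); ``max_models`` caps the catalog;
    ``max_candidates`` caps the number of candidate tables examined
    (the search reports a partial catalog when exhausted);
    ``propagate`` toggles steady-state constraint propagation.
    """

    snoussi: bool = False
    observability: bool = False
    holds_mode: str = "all_states"
    max_models: int = 1000
    max_candidates: int = 2_000_000
    propagate: bool = True
    progress_logging: bool = False

    def __post_init__(self) -> None:
        if self.max_models < 1:
            raise ValueError("max_models must be >= 1")


@dataclass
class ModelCatalog:
    """Ordered collection of parameter sets satisfying a specification.

    ``complete`` is False when a search cap was exhausted before the whole
    candidate space was examined.
    """

    network: RegulatoryNetwork
    parameter_sets: List[ParameterSet]
    complete: bool = True
    candidates_checked: int = 0

    @property
    def labels(self) -> List[str]:
        return [f"M{i + 1}" for i in range(len(self.parameter_sets))]

    def __len__(self) -> int:
        return len(self.parameter_sets)

    def __iter__(self):
        return iter(self.parameter_sets)


class EnumerationCapExceeded(RuntimeError):
    """Raised by callers that require a complete catalog when it is partial."""


def _conjunction_atoms(f: CtlFormula) -> Optional[List[Atom]]:
    """Flatten a pure conjunction of atoms, else None."""
    if isinstance(f, Atom):
        return [f]
    if isinstance(f, And):
        left = _conjunction_atoms(f.left)
        right = _conjunction_atoms(f.right)
        if left is not None and right is not None:
            return left + right
    return None


def _ag_conjunctions(f: CtlFormula) -> List[List[Atom]]:
    out = []
    stack = [f]
    while stack:
        node = stack.pop()
        if isinstance(node, Temporal) and node.op == "AG":
            atoms = _conjunction_atoms(node.operand)
            if atoms is not None:
                out.append(atoms)
        stack.extend(node.children())
    return out


def forced_entries(
    net: RegulatoryNetwork, spec: CtlFormula
) -> Dict[Tuple[str, FrozenSet[str]], int]:
    """K entries forced by steady-state propagation from the specification.

    For each ``AG(c)`` with ``c`` a conjunction of atoms: any state in a
    nonempty AG(c)-closed region keeps every entity named in ``c`` steady.
    When an entity's resource set is identical in *all* completions of ``c``
    (the unnamed entities ranging freely), the corresponding K entry must
    equal the level ``c`` assigns.  This assumes each AG target must actually
    be realized somewhere, which is the case whenever the specification's
    implications have satisfiable antecedents and are checked in
    ``all_states`` mode; candidates are re-verified exactly afterwards.
    """
    forced: Dict[Tuple[str, FrozenSet[str]], int] = {}
    names = net.entity_names
    for atoms in _ag_conjunctions(spec):
        assigned: Dict[str, int] = {}
        consistent = True
        for a in atoms:
            if a.entity in assigned and assigned[a.entity] != a.level:
                consistent = False  # contradictory conjunction: AG target empty
                break
            assigned[a.entity] = a.level
        if not consistent:
            continue
        free = [n for n in names if n not in assigned]
        free_ranges = [range(net.entities[net.index(n)].max_level + 1) for n in free]
        for entity, level in assigned.items():
            resource_sets = set()
            for combo in itertools.product(*free_ranges):
                levels = dict(zip(free, combo))
                levels.update(assigned)
                state = tuple(levels[n] for n in names)
                from .network import resources

                resource_sets.add(resources(net, state, entity))
                if len(resource_sets) > 1:
                    break
            if len(resource_sets) == 1:
                key = (entity, next(iter(resource_sets)))
                if key in forced and forced[key] != level:
                    raise ValueError(
                        f"specification forces contradictory values for K_{entity}"
                        f"({sorted(key[1])})"
                    )
                forced[key] = level
    return forced


def _entity_tables(
    net: RegulatoryNetwork,
    entity: str,
    forced: Dict[Tuple[str, FrozenSet[str]], int],
    snoussi: bool,
) -> List[Dict[FrozenSet[str], int]]:
    """All K tables for one entity consistent with forcing (deterministic order)."""
    max_level = net.entities[net.index(entity)].max_level
    subsets = _subsets(net.regulators(entity))
    choices = []
    for w in subsets:
        key = (entity, w)
        if key in forced:
            choices.append([forced[key]])
        else:
            choices.append(list(range(max_level + 1)))
    out = []
    for combo in itertools.product(*choices):
        table = dict(zip(subsets, combo))
        if snoussi:
            ok = all(
                table[w1] <= table[w2]
                for w1 in subsets
                for w2 in subsets
                if w1 < w2
            )
            if not ok:
                continue
        out.append(table)
    return out


def satisfies_spec(
    net: RegulatoryNetwork,
    params: ParameterSet,
    spec: CtlFormula,
    options: Optional[EnumerationOptions] = None,
) -> bool:
    """Would ``params`` be a member of the catalog for ``spec``?

    Checks the structural side conditions and the CTL verdict exactly — the
    membership test used for catalog re-verification.
    """
    options = options or EnumerationOptions()
    report = validate_parameter_set(
        net, params, snoussi=options.snoussi, observability=options.observability
    )
    if not report.ok:
        return False
    graph = build_state_graph(ModelInstance(net, params))
    return holds(graph, spec, mode=options.holds_mode)


def enumerate_parameter_sets(
    net: RegulatoryNetwork,
    spec: CtlFormula,
    options: Optional[EnumerationOptions] = None,
) -> ModelCatalog:
    """Exhaustively enumerate parameter sets satisfying ``spec``.

    Candidates are generated in lexicographic order over the flattened K
    vector (entity order, resource subsets by size then lexicographically),
    so catalog labels M1..Mn are deterministic.  The search stops early when
    ``max_models`` or ``max_candidates`` is reached, returning a partial
    catalog flagged ``complete=False``.
    """
    options = options or EnumerationOptions()
    forced = forced_entries(net, spec) if options.propagate else {}
    per_entity = [
        _entity_tables(net, e.name, forced, options.snoussi) for e in net.entities
    ]
    found: List[ParameterSet] = []
    checked = 0
    complete = True
    for combo in itertools.product(*per_entity):
        if checked >= options.max_candidates or len(found) >= options.max_models:
            complete = False
            break
        checked += 1
        params = ParameterSet(
            {e.name: dict(tab) for e, tab in zip(net.entities, combo)}
        )
        if options.observability:
            report = validate_parameter_set(net, params, observability=True)
            if not report.ok:
                continue
        graph = build_state_graph(ModelInstance(net, params))
        if holds(graph, spec, mode=options.holds_mode):
            found.append(params)
        if options.progress_logging and checked % 10000 == 0:  # pragma: no cover
            print(f"checked {checked} candidates, {len(found)} models")
    return ModelCatalog(net, found, complete=complete, candidates_checked=checked)


def parameter_table(catalog: ModelCatalog) -> pd.DataFrame:
    """Rectangular K table: one row per parameter, one column per model.

    Row labels read ``K_<entity>{<resources>}``; row order is entity order,
    then resource subsets by size then lexicographically — ready for CSV
    export or heatmap plotting.
    """
    if not catalog.parameter_sets:
        raise ValueError("empty catalog")
    net = catalog.network
    rows = []
    index = []
    for ent in net.entities:
        for w in _subsets(net.regulators(ent.name)):
            index.append(f"K_{ent.name}{{{','.join(sorted(w))}}}")
            rows.append([ps.table[ent.name][w] for ps in catalog.parameter_sets])
    return pd.DataFrame(rows, index=index, columns=catalog.labels)


@dataclass
class SelectionCriteria:
    """Criteria for picking one model out of a catalog.

    ``unique_deadlock_at``: fixed points must be exactly this one state.
    ``fixed_points_exactly``: fixed points must be exactly this state list.
    ``require_cycle_through``: the listed states must form a closed walk.
    ``require_reach``: list of (source, targets) — some target reachable.
    ``require_bifurcation_at``: each listed state must be a strict
    bifurcation state (two successors with different reachable-attractor
    sets) outside every attractor.
    """

    unique_deadlock_at: Optional[State] = None
    fixed_points_exactly: Optional[Sequence[State]] = None
    require_cycle_through: Optional[Sequence[State]] = None
    require_reach: List[Tuple[State, Sequence[State]]] = field(default_factory=list)
    require_bifurcation_at: List[State] = field(default_factory=list)


class NoModelMeetsCriteria(LookupError):
    """Raised when no catalog member satisfies the selection criteria;
    carries per-member failure diagnostics."""

    def __init__(self, failures: Dict[str, List[str]]):
        lines = [f"{label}: {'; '.join(why)}" for label, why in failures.items()]
        super().__init__("no catalog member meets the criteria:\n" + "\n".join(lines))
        self.failures = failures


def _criteria_failures(model: ModelInstance, criteria: SelectionCriteria) -> List[str]:
    import networkx as nx

    why: List[str] = []
    fps = fixed_points(model)
    if criteria.unique_deadlock_at is not None:
        if fps != [tuple(criteria.unique_deadlock_at)]:
            why.append(f"fixed points {fps} != [{tuple(criteria.unique_deadlock_at)}]")
    if criteria.fixed_points_exactly is not None:
        want = sorted(tuple(s) for s in criteria.fixed_points_exactly)
        if fps != want:
            why.append(f"fixed points {fps} != {want}")
    graph = None
    if criteria.require_cycle_through or criteria.require_reach or criteria.require_bifurcation_at:
        graph = build_state_graph(model)
    if criteria.require_cycle_through:
        walk = [tuple(s) for s in criteria.require_cycle_through]
        edges = list(zip(walk, walk[1:] + walk[:1]))
        missing = [e for e in edges if not graph.graph.has_edge(*e)]
        if missing:
            why.append(f"cycle walk broken at {missing[0]}")
    if criteria.require_reach:
        for src, targets in criteria.require_reach:
            src = tuple(src)
            tset = {tuple(t) for t in targets}
            reach = nx.descendants(graph.graph, src) | {src}
            if not reach & tset:
                why.append(f"no path from {src} to any of the required targets")
    if criteria.require_bifurcation_at:
        atts = attractors(graph)
        att_states = set().union(*(a.states for a in atts)) if atts else set()
        for s in criteria.require_bifurcation_at:
            s = tuple(s)
            if s in att_states:
                why.append(f"{s} lies inside an attractor")
                continue
            reach_sets = set()
            for t in graph.graph.successors(s):
                r = nx.descendants(graph.graph, t) | {t}
                reach_sets.add(frozenset(i for i, a in enumerate(atts) if a.states & r))
            if len(reach_sets) < 2:
                why.append(f"{s} is not a bifurcation state")
    return why


def select_model(catalog: ModelCatalog, criteria: SelectionCriteria) -> ModelInstance:
    """First catalog member (deterministic order) meeting all criteria."""
    if not catalog.parameter_sets:
        raise ValueError("empty catalog")
    failures: Dict[str, List[str]] = {}
    for label, params in zip(catalog.labels, catalog.parameter_sets):
        model = ModelInstance(catalog.network, params)
        why = _criteria_failures(model, criteria)
        if not why:
            return model
        failures[label] = why
    raise NoModelMeetsCriteria(failures)
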