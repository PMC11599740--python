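"""Regulatory-network data model in the Thomas (kinetic logic) formalism.

A biological regulatory network (BRN) is a signed, thresholded directed graph
over named entities.  Each entity carries a maximum discrete expression level
``max_level`` (1 for a Boolean entity); each interaction carries a sign
(``"+"`` activation, ``"-"`` inhibition) and an integer threshold.  The
discrete dynamics downstream are driven by *resources*: a regulator counts as
a resource of its target when it is an activator at or above its threshold,
or an inhibitor below its threshold.  A complete table of logical parameters
K_v(ω) — one target level per entity ``v`` and resource subset ``ω`` of its
regulators — then fully specifies the asynchronous dynamics (see
:mod:`qualdyn.dynamics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

__all__ = [
    "Entity",
    "Interaction",
    "RegulatoryNetwork",
    "ParameterSet",
    "ValidationReport",
    "NetworkValidationError",
    "DuplicateEntityError",
    "UnknownEntityError",
    "ThresholdError",
    "IncompleteParameterSetError",
    "normalize_name",
    "build_network",
    "resources",
    "state_count",
    "validate_parameter_set",
]

#: Alternative spellings accepted when parsing formula text.  The literature
#: (and the CTL dialect used for the HIF-1 case study) mixes plain-ASCII and
#: canonical spellings for a few entities.
NAME_ALIASES: Dict[str, str] = {
    "GLUT1": "GLUT-1",
    "P53": "p53",
    "BCAT": "β-catenin",
    "CMYC": "C-MYC",
    "HIF1": "HIF-1",
}


def normalize_name(name: str, known: Iterable[str] = ()) -> str:
    """Map an alternative spelling to its canonical entity name.

    Names are case-sensitive identifiers (hyphens allowed).  ``known`` names
    pass through untouched; otherwise the alias table is consulted.
    """
    name = name.strip()
    if name in set(known):
        return name
    return NAME_ALIASES.get(name, name)


class NetworkValidationError(ValueError):
    """Base class for model-validation failures."""


class DuplicateEntityError(NetworkValidationError):
    pass


class UnknownEntityError(NetworkValidationError):
    pass


class ThresholdError(NetworkValidationError):
    pass


class IncompleteParameterSetError(NetworkValidationError):
    pass


@dataclass(frozen=True)
class Entity:
    """A network node with a discrete level range ``0..max_level``."""

    name: str
    max_level: int = 1

    def __post_init__(self) -> None:
        if not self.name:
            raise NetworkValidationError("entity name must be non-empty")
        if self.max_level < 1:
            raise NetworkValidationError(
                f"entity {self.name!r}: max_level must be >= 1, got {self.max_level}"
            )


@dataclass(frozen=True)
class Interaction:
    """A signed, thresholded directed edge ``source -> target``."""

    source: str
    target: str
    sign: str  # "+" activation, "-" inhibition
    threshold: int = 1

    def __post_init__(self) -> None:
        if self.sign not in ("+", "-"):
            raise NetworkValidationError(
                f"interaction {self.source}->{self.target}: sign must be '+' or '-', "
                f"got {self.sign!r}"
            )
        if self.threshold < 1:
            raise ThresholdError(
                f"interaction {self.source}->{self.target}: threshold must be >= 1"
            )


class RegulatoryNetwork:
    """A validated BRN with a stable, user-given entity order.

    The entity order defines the coordinate order of every qualitative state
    vector downstream — states are plain tuples of ints in this order.
    """

    def __init__(self, entities: Sequence[Entity], interactions: Sequence[Interaction]):
        names = [e.name for e in entities]
        seen = set()
        for n in names:
            if n in seen:
                raise DuplicateEntityError(f"duplicate entity name {n!r}")
            seen.add(n)
        self.entities: Tuple[Entity, ...] = tuple(entities)
        self._index: Dict[str, int] = {n: i for i, n in enumerate(names)}
        by_pair = {}
        for ia in interactions:
            for endpoint in (ia.source, ia.target):
                if endpoint not in self._index:
                    raise UnknownEntityError(
                        f"interaction {ia.source}->{ia.target}: unknown entity {endpoint!r}"
                    )
            src_max = self.entities[self._index[ia.source]].max_level
            if ia.threshold > src_max:
                raise ThresholdError(
                    f"interaction {ia.source}->{ia.target}: threshold {ia.threshold} "
                    f"exceeds max_level({ia.source}) = {src_max}"
                )
            key = (ia.source, ia.target)
            if key in by_pair:
                raise NetworkValidationError(
                    f"multiple interactions for ordered pair {ia.source}->{ia.target}"
                )
            by_pair[key] = ia
        self.interactions: Tuple[Interaction, ...] = tuple(interactions)
        # predecessor lists in entity order of the source, for determinism
        self._preds: Dict[str, Tuple[Interaction, ...]] = {n: () for n in names}
        self._succs: Dict[str, Tuple[Interaction, ...]] = {n: () for n in names}
        for n in names:
            self._preds[n] = tuple(
                sorted(
                    (ia for ia in interactions if ia.target == n),
                    key=lambda ia: self._index[ia.source],
                )
            )
            self._succs[n] = tuple(
                sorted(
                    (ia for ia in interactions if ia.source == n),
                    key=lambda ia: self._index[ia.target],
                )
            )

    # -- basic accessors -------------------------------------------------
    @property
    def entity_names(self) -> Tuple[str, ...]:
        return tuple(e.name for e in self.entities)

    @property
    def max_levels(self) -> Tuple[int, ...]:
        return tuple(e.max_level for e in self.entities)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise UnknownEntityError(f"unknown entity {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __len__(self) -> int:
        return len(self.entities)

    def predecessors(self, name: str) -> Tuple[Interaction, ...]:
        """Incoming interactions of ``name`` (G⁻), in entity order of sources."""
        self.index(name)
        return self._preds[name]

    def successors(self, name: str) -> Tuple[Interaction, ...]:
        """Outgoing interactions of ``name`` (G⁺), in entity order of targets."""
        self.index(name)
        return self._succs[name]

    def regulators(self, name: str) -> Tuple[str, ...]:
        return tuple(ia.source for ia in self.predecessors(name))

    def check_state(self, state: Sequence[int]) -> Tuple[int, ...]:
        state = tuple(state)
        if len(state) != len(self.entities):
            raise NetworkValidationError(
                f"state has {len(state)} coordinates, expected {len(self.entities)}"
            )
        for lvl, ent in zip(state, self.entities):
            if not 0 <= lvl <= ent.max_level:
                raise NetworkValidationError(
                    f"level {lvl} of entity {ent.name!r} outside [0, {ent.max_level}]"
                )
        return state

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"RegulatoryNetwork({len(self.entities)} entities, "
            f"{len(self.interactions)} interactions)"
        )


def build_network(
    entity_specs: Sequence[Tuple[str, int]],
    interaction_specs: Sequence[Tuple[str, str, str, int]],
) -> RegulatoryNetwork:
    """Build and validate a network from plain tuples.

    ``entity_specs`` is an ordered list of ``(name, max_level)``;
    ``interaction_specs`` a list of ``(source, target, sign, threshold)``.
    The entity order given here is preserved and defines state-vector
    coordinates everywhere downstream.
    """
    entities = [Entity(n, lvl) for n, lvl in entity_specs]
    interactions = [Interaction(s, t, sign, thr) for s, t, sign, thr in interaction_specs]
    return RegulatoryNetwork(entities, interactions)


def resources(
    net: RegulatoryNetwork, state: Sequence[int], target: str
) -> FrozenSet[str]:
    """Resource set of ``target`` in ``state``.

    A regulator ``u`` of ``target`` is a resource when it is an activator at
    or above its threshold, or an inhibitor strictly below its threshold
    (the *absence* of an inhibitor counts as a resource).
    """
    state = net.check_state(state)
    out = []
    for ia in net.predecessors(target):
        level = state[net.index(ia.source)]
        if ia.sign == "+":
            if level >= ia.threshold:
                out.append(ia.source)
        else:
            if level < ia.threshold:
                out.append(ia.source)
    return frozenset(out)


def state_count(net: RegulatoryNetwork) -> int:
    """Number of qualitative states: the product of (max_level + 1)."""
    z = 1
    for e in net.entities:
        z *= e.max_level + 1
    return z


def _subsets(items: Sequence[str]) -> List[FrozenSet[str]]:
    """All subsets, ordered by size then lexicographically (deterministic)."""
    out: List[FrozenSet[str]] = []
    items = sorted(items)
    for k in range(len(items) + 1):
        for combo in combinations(items, k):
            out.append(frozenset(combo))
    return out


class ParameterSet:
    """Complete table of logical parameters K_v(ω).

    ``table`` maps entity name -> {resource subset (frozenset of names) ->
    target level K}.  An entity with no regulators has the single entry for
    the empty set, which acts as a constant target.
    """

    def __init__(self, table: Dict[str, Dict[FrozenSet[str], int]]):
        self.table: Dict[str, Dict[FrozenSet[str], int]] = {
            v: {frozenset(w): int(k) for w, k in sub.items()} for v, sub in table.items()
        }

    def k(self, entity: str, resource_set: Iterable[str]) -> int:
        try:
            return self.table[entity][frozenset(resource_set)]
        except KeyError:
            raise IncompleteParameterSetError(
                f"no logical parameter K_{entity}({sorted(resource_set)})"
            ) from None

    def check_complete(self, net: RegulatoryNetwork) -> None:
        """Raise unless exactly one K entry exists per entity and subset."""
        for ent in net.entities:
            regs = net.regulators(ent.name)
            expected = set(_subsets(regs))
            got = set(self.table.get(ent.name, {}))
            missing = expected - got
            extra = got - expected
            if missing or extra:
                raise IncompleteParameterSetError(
                    f"entity {ent.name!r}: "
                    + (f"missing subsets {sorted(map(sorted, missing))} " if missing else "")
                    + (f"unexpected subsets {sorted(map(sorted, extra))}" if extra else "")
                )

    def items_ordered(self, net: RegulatoryNetwork):
        """Deterministic iteration: entity order, subsets by size then lex."""
        for ent in net.entities:
            for w in _subsets(net.regulators(ent.name)):
                yield ent.name, w, self.table[ent.name][w]

    def flat_values(self, net: RegulatoryNetwork) -> Tuple[int, ...]:
        return tuple(k for _, _, k in self.items_ordered(net))

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self.table == other.table

    def __hash__(self):
        return hash(
            tuple(
                sorted(
                    (v, tuple(sorted((tuple(sorted(w)), k) for w, k in sub.items())))
                    for v, sub in self.table.items()
                )
            )
        )

    def __repr__(self) -> str:  # pragma: no cover
        n = sum(len(sub) for sub in self.table.values())
        return f"ParameterSet({len(self.table)} entities, {n} parameters)"


@dataclass
class ValidationReport:
    """Result of structural parameter-set validation."""

    ok: bool = True
    violations: List[Tuple[str, str, str]] = field(default_factory=list)
    # (rule name, entity, human-readable detail)

    def add(self, rule: str, entity: str, detail: str) -> None:
        self.ok = False
        self.violations.append((rule, entity, detail))


def validate_parameter_set(
    net: RegulatoryNetwork,
    params: ParameterSet,
    *,
    snoussi: bool = False,
    observability: bool = False,
) -> ValidationReport:
    """Validate a parameter set against a network.

    Completeness and level-range violations are always checked (an incomplete
    table is a hard error, not a report entry).  With ``snoussi`` the report
    also flags non-monotone K tables (K must be non-decreasing under
    resource-subset inclusion); with ``observability`` it flags interactions
    that never change any K value.  Both side conditions are off by default:
    the HIF-1 case-study parameters deliberately violate Snoussi monotonicity
    for AKT.
    """
    params.check_complete(net)
    report = ValidationReport()
    for ent in net.entities:
        sub = params.table[ent.name]
        for w, k in sub.items():
            if not 0 <= k <= ent.max_level:
                report.add(
                    "range",
                    ent.name,
                    f"K({sorted(w)}) = {k} outside [0, {ent.max_level}]",
                )
        if snoussi:
            subsets = _subsets(net.regulators(ent.name))
            for w1 in subsets:
                for w2 in subsets:
                    if w1 < w2 and sub[w1] > sub[w2]:
                        report.add(
                            "snoussi",
                            ent.name,
                            f"K({sorted(w1)}) = {sub[w1]} > K({sorted(w2)}) = {sub[w2]}",
                        )
    if observability:
        for ia in net.interactions:
            regs = [r for r in net.regulators(ia.target) if r != ia.source]
            sub = params.table[ia.target]
            effective = any(
                sub[frozenset(w)] != sub[frozenset(w) | {ia.source}]
                for w in _subsets(regs)
            )
            if not effective:
                report.add(
                    "observability",
                    ia.target,
                    f"interaction {ia.source}->{ia.target} never changes K",
                )
    return report
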