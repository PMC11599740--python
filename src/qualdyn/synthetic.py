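"""Random model generators for pipeline testing.

Emits networks, parameter tables and kinetics with the structural properties
the analysis assumes: signed thresholded interaction graphs in which every
entity has at least one regulator, complete logical-parameter tables
(optionally Snoussi-monotone), and positive kinetic rate constants.  All
sampling is integer-based on a seeded :class:`random.Random`, so identical
configuration and seed give identical output on every platform.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Tuple

import networkx as nx

from .network import ParameterSet, RegulatoryNetwork, build_network, _subsets

__all__ = [
    "GeneratorConfig",
    "random_network",
    "random_parameters",
    "random_kinetics",
    "no_positive_circuit_network",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling parameters for random regulatory networks."""

    n_entities: int
    edge_probability: float = 0.3
    inhibition_probability: float = 0.3
    max_level: int = 1
    snoussi_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_entities < 1:
            raise ValueError("n_entities must be >= 1")
        for p in (self.edge_probability, self.inhibition_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.max_level < 1:
            raise ValueError("max_level must be >= 1")


def _entity_names(n: int) -> List[str]:
    return [f"v{i}" for i in range(n)]


def random_network(config: GeneratorConfig) -> RegulatoryNetwork:
    """Sample a signed thresholded network.

    Every ordered pair of distinct entities receives an edge with
    ``edge_probability``; signs are inhibitory with
    ``inhibition_probability``; thresholds are uniform on
    ``[1, max_level]``.  Entities left without a regulator get a self-input
    of random sign so the dynamics are well defined everywhere (the regime
    the packaged case study occupies: every entity regulated).
    """
    rng = random.Random(config.seed)
    names = _entity_names(config.n_entities)
    edges = []
    has_pred = {n: False for n in names}
    for src in names:
        for tgt in names:
            if src == tgt:
                continue
            if rng.random() < config.edge_probability:
                sign = "-" if rng.random() < config.inhibition_probability else "+"
                thr = rng.randint(1, config.max_level)
                edges.append((src, tgt, sign, thr))
                has_pred[tgt] = True
    for n in names:
        if not has_pred[n]:
            sign = "-" if rng.random() < config.inhibition_probability else "+"
            edges.append((n, n, sign, rng.randint(1, config.max_level)))
    return build_network([(n, config.max_level) for n in names], edges)


def random_parameters(
    net: RegulatoryNetwork, snoussi_only: bool = False, seed: int = 0
) -> ParameterSet:
    """Sample a complete K table, uniformly or by monotone completion.

    With ``snoussi_only`` the table is built subset-by-subset in inclusion-
    compatible order, each K drawn uniformly from
    ``[max over strict subsets, max_level]`` — the result always passes the
    Snoussi validator.
    """
    rng = random.Random(seed)
    table: Dict[str, Dict[FrozenSet[str], int]] = {}
    for ent in net.entities:
        sub: Dict[FrozenSet[str], int] = {}
        for w in _subsets(net.regulators(ent.name)):  # size order: subsets first
            if snoussi_only:
                lo = max(
                    (sub[w2] for w2 in sub if w2 < w),
                    default=0,
                )
                sub[w] = rng.randint(lo, ent.max_level)
            else:
                sub[w] = rng.randint(0, ent.max_level)
        table[ent.name] = sub
    return ParameterSet(table)


def random_kinetics(net: RegulatoryNetwork, seed: int = 0) -> "KineticParameters":
    """Sample positive rate constants for the ODE translation."""
    from .ode import KineticParameters

    rng = random.Random(seed)

    def u(lo: int, hi: int, scale: float) -> float:
        return rng.randint(lo, hi) / scale  # integer-based for reproducibility

    return KineticParameters(
        beta={e.name: u(5, 20, 10) for e in net.entities},
        gamma={e.name: u(5, 20, 10) for e in net.entities},
        x0={e.name: u(0, 10, 10) for e in net.entities},
        theta={(ia.source, ia.target): u(3, 8, 10) for ia in net.interactions},
        hill={(ia.source, ia.target): float(rng.randint(2, 6)) for ia in net.interactions},
    )


def _has_positive_circuit(net: RegulatoryNetwork) -> bool:
    g = nx.DiGraph()
    sign = {}
    for ia in net.interactions:
        g.add_edge(ia.source, ia.target)
        sign[(ia.source, ia.target)] = 1 if ia.sign == "+" else -1
    for cyc in nx.simple_cycles(g):
        prod = 1
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            prod *= sign[(a, b)]
        if prod > 0:
            return True
    return False


def no_positive_circuit_network(
    config: GeneratorConfig, max_tries: int = 1000
) -> RegulatoryNetwork:
    """Rejection-sample a network with no positive circuit.

    Powers the multistationarity property check (without a positive circuit
    a Boolean network with Snoussi-monotone parameters has at most one fixed
    point).  Tries seeds ``config.seed, config.seed + 1, ...``.
    """
    for k in range(max_tries):
        cand = random_network(
            GeneratorConfig(
                n_entities=config.n_entities,
                edge_probability=config.edge_probability,
                inhibition_probability=config.inhibition_probability,
                max_level=config.max_level,
                snoussi_only=config.snoussi_only,
                seed=config.seed + k,
            )
        )
        if not _has_positive_circuit(cand):
            return cand
    raise RuntimeError(
        f"no positive-circuit-free network found in {max_tries} attempts"
    )
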