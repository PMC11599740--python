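"""Readers, writers and exporters for package formats.

Model files are JSON or YAML with keys ``entities`` (name, max_level),
``interactions`` (source, target, sign, threshold), optional ``parameters``
(entity -> list of {resources, K}) and a required explicit ``entity_order``
that pins state-vector coordinates.  States serialize as undelimited digit
strings in entity order (``"111110111"``), which sort lexicographically.

State graphs export to GraphML, DOT and CSV edge lists, optionally carrying
a ``betweenness`` node attribute for external viewers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import networkx as nx
import yaml

from .dynamics import ModelInstance, StateGraph
from .network import (
    NetworkValidationError,
    ParameterSet,
    RegulatoryNetwork,
    build_network,
    _subsets,
)

__all__ = [
    "state_to_string",
    "string_to_state",
    "model_to_dict",
    "dict_to_model",
    "read_model",
    "write_model",
    "export_state_graph",
]

State = Tuple[int, ...]


def state_to_string(state: Sequence[int]) -> str:
    """Serialize a state as an undelimited digit string in entity order."""
    return "".join(str(x) for x in state)


def string_to_state(text: str) -> State:
    """Parse a digit-string state (single digits per coordinate)."""
    if not text.isdigit():
        raise NetworkValidationError(f"malformed state string {text!r}")
    return tuple(int(c) for c in text)


def model_to_dict(
    net: RegulatoryNetwork, params: Optional[ParameterSet] = None
) -> dict:
    """Canonical serializable form of a network (and optional parameters)."""
    out = {
        "entity_order": list(net.entity_names),
        "entities": [
            {"name": e.name, "max_level": e.max_level} for e in net.entities
        ],
        "interactions": [
            {
                "source": ia.source,
                "target": ia.target,
                "sign": ia.sign,
                "threshold": ia.threshold,
            }
            for ia in net.interactions
        ],
    }
    if params is not None:
        out["parameters"] = {
            ent.name: [
                {"resources": sorted(w), "K": params.table[ent.name][w]}
                for w in _subsets(net.regulators(ent.name))
            ]
            for ent in net.entities
        }
    return out


def dict_to_model(
    data: dict,
) -> Union[RegulatoryNetwork, ModelInstance]:
    """Validate and build a network or full model from its dict form."""
    for key in ("entities", "interactions", "entity_order"):
        if key not in data:
            raise NetworkValidationError(f"model file missing key {key!r}")
    ents = data["entities"]
    order = list(data["entity_order"])
    by_name = {e["name"]: e for e in ents}
    if sorted(by_name) != sorted(order):
        raise NetworkValidationError(
            "entity_order inconsistent with the entities list"
        )
    entity_specs = [(n, int(by_name[n].get("max_level", 1))) for n in order]
    interaction_specs = []
    for ia in data["interactions"]:
        sign = ia["sign"]
        if sign not in ("+", "-"):
            raise NetworkValidationError(
                f"unknown sign token {sign!r} in interaction "
                f"{ia.get('source')}->{ia.get('target')}"
            )
        interaction_specs.append(
            (ia["source"], ia["target"], sign, int(ia.get("threshold", 1)))
        )
    net = build_network(entity_specs, interaction_specs)
    if "parameters" not in data:
        return net
    table: Dict[str, Dict[frozenset, int]] = {}
    for name, entries in data["parameters"].items():
        if name not in net:
            raise NetworkValidationError(f"parameters for unknown entity {name!r}")
        table[name] = {
            frozenset(e["resources"]): int(e["K"]) for e in entries
        }
    params = ParameterSet(table)
    return ModelInstance(net, params)


def read_model(path) -> Union[RegulatoryNetwork, ModelInstance]:
    """Load a model file (JSON by extension, else YAML).

    Returns a :class:`ModelInstance` when the file carries parameters, else
    the bare :class:`RegulatoryNetwork`.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise NetworkValidationError(f"{path}: model file must be a mapping")
    try:
        return dict_to_model(data)
    except NetworkValidationError as err:
        raise NetworkValidationError(f"{path}: {err}") from err


def write_model(
    target, net_or_model: Union[RegulatoryNetwork, ModelInstance]
) -> None:
    """Write the canonical serialization (round-trips through read_model)."""
    if isinstance(net_or_model, ModelInstance):
        data = model_to_dict(net_or_model.network, net_or_model.parameters)
    else:
        data = model_to_dict(net_or_model)
    path = Path(target)
    if path.suffix.lower() == ".json":
        text = json.dumps(data, indent=1, ensure_ascii=False) + "\n"
    else:
        text = yaml.safe_dump(data, allow_unicode=True, sort_keys=False)
    path.write_text(text, encoding="utf-8")


def _labeled_graph(graph: StateGraph, cmap) -> nx.DiGraph:
    g = nx.DiGraph()
    for s in graph.states:
        label = state_to_string(s)
        attrs = {}
        if cmap is not None:
            attrs["betweenness"] = float(cmap[s])
        g.add_node(label, **attrs)
    for a, b in sorted(graph.graph.edges()):
        g.add_edge(state_to_string(a), state_to_string(b))
    return g


def export_state_graph(
    graph: StateGraph,
    path,
    fmt: str = "graphml",
    cmap=None,
) -> None:
    """Export a state graph with digit-string node labels.

    ``fmt`` is ``graphml``, ``dot`` or ``csv`` (two-column edge list).
    Node and edge order is deterministic, so exports are byte-stable.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(_labeled_graph(graph, cmap), path)
        return
    if fmt == "dot":
        lines = ["digraph stategraph {"]
        for s in graph.states:
            if cmap is not None:
                lines.append(
                    f'  "{state_to_string(s)}" [betweenness={float(cmap[s]):.6f}];'
                )
            else:
                lines.append(f'  "{state_to_string(s)}";')
        for a, b in sorted(graph.graph.edges()):
            lines.append(f'  "{state_to_string(a)}" -> "{state_to_string(b)}";')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return
    if fmt == "csv":
        lines = ["source,target"]
        for a, b in sorted(graph.graph.edges()):
            lines.append(f"{state_to_string(a)},{state_to_string(b)}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return
    raise ValueError(f"unknown export format {fmt!r}")
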