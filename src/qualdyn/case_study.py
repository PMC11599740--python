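"""The nine-entity HIF-1 cancer-signaling case study.

Packages the Boolean regulatory network over (HIF-1, ERK, VEGF, p53,
β-catenin, AKT, GLUT-1, C-MYC, OGT) — hypoxia master regulator, proliferation
kinase, angiogenic growth factor, tumor suppressor, Wnt effector, survival
kinase, glucose transporter, oncogenic transcription factor and O-GlcNAc
transferase — with fourteen signed interactions, the selected logical
parameter set, the temporal-logic observation formulas, and every reference
qualitative state used by the analysis:

* the pathogenic deadlock ``111110111`` (everything active except AKT),
* the homeostatic recovery state ``000001000`` (only AKT active),
* the twelve-state homeostatic cycle in which p53, β-catenin and AKT stay
  active while all other entities oscillate,
* seven bifurcation states from which both fates remain reachable.

The selected parameter set was identified by CTL-constrained enumeration and
model selection (deterministic first member satisfying the stable-state,
cycle and bifurcation criteria) and is frozen here as package data so that
downstream fixtures are stable.  Note the deliberate non-monotonicity for
AKT — K_AKT(∅)=1 but K_AKT({VEGF})=0 — required for the deadlock and
recovery states to both be steady; the model therefore fails the Snoussi
side condition by design.

The model has *two* fixed points: the pathogenic deadlock and the
homeostatic recovery state.  The recovery state's stability is a logical
consequence of the homeostasis observation formula (its stable region keeps
six entities clamped while the remaining three relax to constant targets),
so a model satisfying the observations cannot have the deadlock as its only
fixed point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Dict, List, Tuple

from . import analysis, ctl, dynamics, io
from .dynamics import ModelInstance
from .network import RegulatoryNetwork

__all__ = [
    "CaseStudyFixtures",
    "load_canonical_model",
    "load_alternative_network",
    "load_fixtures",
    "load_ctl_formulas",
    "ctl_conjunction",
    "recovery_labels",
    "reproduce_report",
]

State = Tuple[int, ...]

_DATA = importlib_resources.files(__package__) / "data"


def _data_text(name: str) -> str:
    return (_DATA / name).read_text(encoding="utf-8")


@dataclass(frozen=True)
class CaseStudyFixtures:
    """The reference qualitative states, in canonical entity order."""

    entity_order: Tuple[str, ...]
    deadlock: State
    recovery: State
    cycle12: Tuple[State, ...]
    bifurcations: Tuple[State, ...]
    trajectory_source: State
    ctl_texts: Tuple[str, ...]


def load_canonical_model() -> ModelInstance:
    """The packaged network plus selected parameter set."""
    data = json.loads(_data_text("hif1.json"))
    model = io.dict_to_model(data)
    assert isinstance(model, ModelInstance)
    return model


def load_alternative_network() -> RegulatoryNetwork:
    """The alternative wiring reading (HIF-1→ERK replacing p53⊣HIF-1).

    The pathway wiring is reported in the literature only as a drawing; two
    reconstructions are text-supported and this is the secondary one (network only, no
    parameters).
    """
    data = json.loads(_data_text("hif1_alt.json"))
    net = io.dict_to_model(data)
    assert isinstance(net, RegulatoryNetwork)
    return net


def load_ctl_formulas(net: RegulatoryNetwork = None) -> List[ctl.CtlFormula]:
    """The three observation formulas, parsed against the canonical network."""
    if net is None:
        net = load_canonical_model().network
    out = []
    for line in _data_text("observations.ctl").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(ctl.parse_ctl(line, net))
    return out


def ctl_conjunction(net: RegulatoryNetwork = None) -> ctl.CtlFormula:
    """All three observation formulas conjoined (the enumeration default)."""
    formulas = load_ctl_formulas(net)
    spec = formulas[0]
    for f in formulas[1:]:
        spec = ctl.And(spec, f)
    return spec


def load_fixtures() -> CaseStudyFixtures:
    data = json.loads(_data_text("fixtures.json"))
    s = io.string_to_state
    return CaseStudyFixtures(
        entity_order=tuple(data["entity_order"]),
        deadlock=s(data["deadlock"]),
        recovery=s(data["recovery"]),
        cycle12=tuple(s(x) for x in data["cycle12"]),
        bifurcations=tuple(s(x) for x in data["bifurcations"]),
        trajectory_source=s(data["trajectory_source"]),
        ctl_texts=tuple(
            line.split("#", 1)[0].strip()
            for line in _data_text("observations.ctl").splitlines()
            if line.split("#", 1)[0].strip()
        ),
    )


def recovery_labels(net: RegulatoryNetwork) -> Dict[int, int]:
    """Coordinate constraints of the homeostatic region (formula 2)."""
    labels = {"VEGF": 0, "OGT": 0, "GLUT-1": 0, "HIF-1": 0, "AKT": 1, "p53": 0}
    return {net.index(n): lvl for n, lvl in labels.items()}


def reproduce_report(out_dir=None) -> dict:
    """Run the full analysis pipeline on the canonical model.

    Checks every packaged reference claim — state count, fixed points, CTL
    verdicts, cycle validity and entity constancy, bifurcation reachability —
    and returns a machine-readable report; with ``out_dir`` given, also
    writes the report (JSON), the state-graph exports and the centrality
    ranking (CSV).  Failed claims are recorded in the report, not raised.
    """
    import networkx as nx

    model = load_canonical_model()
    net = model.network
    fx = load_fixtures()
    claims: Dict[str, dict] = {}

    def claim(name, computed, expected, ok=None):
        ok = (computed == expected) if ok is None else ok
        claims[name] = {"computed": computed, "expected": expected, "ok": bool(ok)}

    graph = dynamics.build_state_graph(model)
    claim("states_total", len(graph.states), 512)

    fps = dynamics.fixed_points(model)
    claim(
        "pathogenic_deadlock_is_fixed_point",
        io.state_to_string(fx.deadlock) in {io.state_to_string(s) for s in fps},
        True,
    )
    claim(
        "fixed_points",
        sorted(io.state_to_string(s) for s in fps),
        sorted([io.state_to_string(fx.deadlock), io.state_to_string(fx.recovery)]),
    )

    formulas = load_ctl_formulas(net)
    verdicts = [ctl.holds(graph, f) for f in formulas]
    claim("ctl_formulas_hold", verdicts, [True, True, True])

    walk = list(fx.cycle12)
    edges = list(zip(walk, walk[1:] + walk[:1]))
    claim("cycle12_closed_walk", all(graph.graph.has_edge(*e) for e in edges), True)
    const_idx = [net.index(n) for n in ("p53", "β-catenin", "AKT")]
    claim(
        "cycle12_constant_entities",
        all(s[i] == 1 for s in walk for i in const_idx),
        True,
    )
    changing = [
        i
        for i in range(len(net))
        if i not in const_idx and len({s[i] for s in walk}) > 1
    ]
    claim("cycle12_oscillating_entities", len(changing), len(net) - 3)

    atts = dynamics.attractors(graph)
    rec_atts = analysis.recovery_attractors(atts, recovery_labels(net))
    rec_states = set().union(*(a.states for a in rec_atts)) if rec_atts else set()
    bif_ok = []
    for b in fx.bifurcations:
        reach = nx.descendants(graph.graph, b) | {b}
        bif_ok.append(fx.deadlock in reach and bool(reach & rec_states))
    claim("bifurcations_reach_both_fates", bif_ok, [True] * len(fx.bifurcations))

    cmap = analysis.betweenness_centrality(graph)
    mean_all = sum(cmap.values()) / len(cmap)
    mean_cycle = sum(cmap[s] for s in walk) / len(walk)
    claim(
        "cycle12_centrality_above_graph_mean",
        round(mean_cycle, 3),
        f"> {round(mean_all, 3)}",
        ok=mean_cycle > mean_all,
    )

    report = {
        "ok": all(c["ok"] for c in claims.values()),
        "claims": claims,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, ensure_ascii=False, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        (out / "report.txt").write_text(
            "\n".join(
                f"{'pass' if c['ok'] else 'FAIL'}  {name}: {c['computed']}"
                for name, c in claims.items()
            )
            + "\n",
            encoding="utf-8",
        )
        io.export_state_graph(graph, out / "state_graph.graphml", "graphml", cmap)
        io.export_state_graph(graph, out / "state_graph.csv", "csv")
        ranked = analysis.rank_states(cmap)
        csv_lines = ["state,betweenness,rank"]
        for r, s in enumerate(ranked, start=1):
            csv_lines.append(f"{io.state_to_string(s)},{cmap[s]:.6f},{r}")
        (out / "centrality.csv").write_text("\n".join(csv_lines) + "\n", "utf-8")
    return report
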