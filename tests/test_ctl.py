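import random

import pytest

import qualdyn as q
from qualdyn import synthetic
from qualdyn.ctl import (
    And,
    Atom,
    BoolConst,
    CtlSyntaxError,
    Implies,
    Not,
    Temporal,
    Until,
    parse_ctl,
    sat_set,
)
from oracles import ctl_sat_bruteforce, random_ctl_formula


class TestParser:
    def test_conjunction_of_atoms(self, hif1_model):
        f = parse_ctl("VEGF = 1 & AKT = 0", hif1_model.network)
        assert isinstance(f, And)
        assert f.left == Atom("VEGF", 1)
        assert f.right == Atom("AKT", 0)

    def test_nested_temporal_shape(self, hif1_model):
        f = parse_ctl("EF(AG(HIF-1 = 1))", hif1_model.network)
        assert isinstance(f, Temporal) and f.op == "EF"
        assert isinstance(f.operand, Temporal) and f.operand.op == "AG"
        assert f.operand.operand == Atom("HIF-1", 1)

    def test_alias_normalization(self, hif1_model):
        f = parse_ctl("GLUT1 = 1 & P53 = 0 & CMYC = 1 & BCAT = 0", hif1_model.network)
        atoms = {a.entity for a in f.atoms()}
        assert atoms == {"GLUT-1", "p53", "C-MYC", "β-catenin"}

    def test_level_out_of_range(self, two_node_net):
        with pytest.raises(CtlSyntaxError):
            parse_ctl("EG(a = 2)", two_node_net)

    def test_unknown_entity(self, two_node_net):
        with pytest.raises(CtlSyntaxError):
            parse_ctl("zz = 1", two_node_net)

    def test_syntax_error_carries_position(self):
        with pytest.raises(CtlSyntaxError) as err:
            parse_ctl("a = 1 & & b = 0")
        assert err.value.position >= 6

    def test_precedence_and_right_associative_implication(self):
        f = parse_ctl("a = 1 & b = 0 | c = 1 -> d = 0 -> e = 1")
        assert isinstance(f, Implies)
        assert isinstance(f.right, Implies)  # right-associative

    def test_until_forms(self, two_node_net):
        f = parse_ctl("E[a = 0 U b = 1]", two_node_net)
        assert isinstance(f, Until) and f.quantifier == "E"
        g = parse_ctl("A[a = 0 U b = 1]", two_node_net)
        assert g.quantifier == "A"

    def test_unicode_operators(self, two_node_net):
        f = parse_ctl("¬(a = 1) ∧ ⊤ ⇒ b = 0", two_node_net)
        assert isinstance(f, Implies)


class TestSemantics:
    def test_ef_reaches_full_state(self, two_node_graph):
        f = parse_ctl("EF(a = 1 & b = 1)")
        assert sat_set(two_node_graph, f) == set(two_node_graph.states)

    def test_ef_false_is_empty(self, two_node_graph):
        assert sat_set(two_node_graph, Temporal("EF", BoolConst(False))) == set()

    def test_top_holds_everywhere(self, two_node_graph):
        assert q.holds(two_node_graph, BoolConst(True), mode="all_states")

    def test_deadlock_satisfies_ag_of_its_own_labels(self, hif1_graph, hif1_fixtures):
        # the implicit self-loop makes AG of the deadlock's labels true there
        f = parse_ctl(
            "AG(VEGF=1 & OGT=1 & GLUT1=1 & HIF-1=1 & AKT=0 & P53=1)",
            hif1_graph.network,
        )
        assert hif1_fixtures.deadlock in sat_set(hif1_graph, f)

    def test_ef_deadlock_from_bifurcation(self, hif1_graph, hif1_fixtures):
        f = parse_ctl(
            "EF(HIF-1=1 & ERK=1 & VEGF=1 & P53=1 & BCAT=1 & AKT=0 & GLUT1=1 & CMYC=1 & OGT=1)",
            hif1_graph.network,
        )
        assert q.holds(hif1_graph, f, mode="at", at=[hif1_fixtures.bifurcations[0]])

    def test_holds_modes(self, two_node_graph):
        f = parse_ctl("a = 1 & b = 1")
        assert not q.holds(two_node_graph, f, mode="all_states")
        assert q.holds(two_node_graph, f, mode="some_state")
        assert q.holds(two_node_graph, f, mode="at", at=[(1, 1)])
        assert not q.holds(two_node_graph, f, mode="at", at=[(0, 0)])


def _random_graph_and_labels(rng, n_entities=2, max_level=1):
    net = synthetic.random_network(
        synthetic.GeneratorConfig(
            n_entities=n_entities,
            edge_probability=0.6,
            max_level=max_level,
            seed=rng.randint(0, 10**6),
        )
    )
    params = synthetic.random_parameters(net, seed=rng.randint(0, 10**6))
    graph = q.build_state_graph(q.ModelInstance(net, params))
    succ = {}
    for s in graph.states:
        nexts = list(graph.graph.successors(s)) or [s]
        succ[s] = nexts
    labels = {
        s: {name: s[i] for i, name in enumerate(net.entity_names)}
        for s in graph.states
    }
    return net, graph, succ, labels


class TestInvariantsAndOracle:
    def test_boolean_dualities(self):
        rng = random.Random(7)
        for _ in range(20):
            net, graph, succ, labels = _random_graph_and_labels(rng)
            phi = random_ctl_formula(rng, net.entity_names, 1, 2)
            all_states = set(graph.states)
            assert sat_set(graph, Not(phi)) == all_states - sat_set(graph, phi)
            ag = sat_set(graph, Temporal("AG", phi))
            ef_not = sat_set(graph, Temporal("EF", Not(phi)))
            assert ag == all_states - ef_not
            af = sat_set(graph, Temporal("AF", phi))
            eg_not = sat_set(graph, Temporal("EG", Not(phi)))
            assert af == all_states - eg_not

    def test_containment_invariants(self):
        rng = random.Random(13)
        for _ in range(20):
            net, graph, _, _ = _random_graph_and_labels(rng)
            phi = random_ctl_formula(rng, net.entity_names, 1, 2)
            s_phi = sat_set(graph, phi)
            assert s_phi <= sat_set(graph, Temporal("EF", phi))
            assert sat_set(graph, Temporal("EG", phi)) <= s_phi

    def test_matches_bruteforce_oracle_on_small_graphs(self):
        # 200+ random formulas of depth <= 4 over random graphs of <= 16 states
        rng = random.Random(42)
        checked = 0
        while checked < 220:
            n_entities = rng.choice([2, 3, 4])
            net, graph, succ, labels = _random_graph_and_labels(rng, n_entities)
            assert len(graph.states) <= 16
            for _ in range(4):
                phi = random_ctl_formula(rng, net.entity_names, 1, rng.randint(1, 4))
                expected = ctl_sat_bruteforce(graph.states, succ, labels, phi)
                assert sat_set(graph, phi) == expected, str(phi)
                checked += 1

    def test_adding_transitions_never_shrinks_ef(self, two_node_model):
        import networkx as nx
        from qualdyn.dynamics import StateGraph

        rng = random.Random(3)
        for _ in range(20):
            net, graph, _, _ = _random_graph_and_labels(rng)
            phi = Temporal("EF", random_ctl_formula(rng, net.entity_names, 1, 2))
            before = sat_set(graph, phi)
            g2 = graph.graph.copy()
            states = graph.states
            for _ in range(3):
                a, b = rng.choice(states), rng.choice(states)
                if a != b:
                    g2.add_edge(a, b)
            bigger = StateGraph(graph.model, g2, states)
            assert before <= sat_set(bigger, phi)


def test_formula_file_roundtrip(tmp_path, two_node_net):
    path = tmp_path / "f.ctl"
    path.write_text("# comment\na = 1 -> EF(b = 1)\n\nAG(a = 0 | b = 0)\n")
    formulas = q.ctl.parse_formula_file(path, two_node_net)
    assert len(formulas) == 2
    assert isinstance(formulas[0], Implies)
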