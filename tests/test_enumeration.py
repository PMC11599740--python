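import itertools

import pytest

import qualdyn as q
from qualdyn import enumeration
from qualdyn.ctl import parse_ctl
from qualdyn.enumeration import (
    EnumerationOptions,
    NoModelMeetsCriteria,
    SelectionCriteria,
    enumerate_parameter_sets,
    forced_entries,
    parameter_table,
    satisfies_spec,
    select_model,
)


def all_boolean_tables(net):
    """Naive enumeration of every complete Boolean K table."""
    from qualdyn.network import _subsets

    per_entity = []
    for ent in net.entities:
        subsets = _subsets(net.regulators(ent.name))
        per_entity.append(
            [dict(zip(subsets, vals)) for vals in itertools.product((0, 1), repeat=len(subsets))]
        )
    for combo in itertools.product(*per_entity):
        yield q.ParameterSet({e.name: dict(t) for e, t in zip(net.entities, combo)})


class TestEnumerate:
    def test_trivial_spec_returns_all_sixteen(self, two_node_net):
        spec = parse_ctl("TRUE", two_node_net)
        catalog = enumerate_parameter_sets(two_node_net, spec)
        assert len(catalog) == 16
        assert catalog.complete

    def test_matches_naive_bruteforce(self, two_node_net):
        spec = parse_ctl("AG(EF(a = 0 & b = 0))", two_node_net)
        catalog = enumerate_parameter_sets(two_node_net, spec)
        expected = [
            ps
            for ps in all_boolean_tables(two_node_net)
            if q.holds(q.build_state_graph(q.ModelInstance(two_node_net, ps)), spec)
        ]
        assert len(catalog) == len(expected)
        assert set(catalog.parameter_sets) == set(expected)

    def test_pruned_equals_naive_on_random_specs(self, two_node_net):
        # propagation must not change the answer, only the work done
        for text in (
            "(a = 1 & b = 1) -> EF(AG(a = 1 & b = 1))",
            "EF(a = 1) & EF(b = 0)",
            "A[a = 0 U b = 1] | AG(a = 0)",
        ):
            spec = parse_ctl(text, two_node_net)
            pruned = enumerate_parameter_sets(two_node_net, spec)
            naive = enumerate_parameter_sets(
                two_node_net, spec, EnumerationOptions(propagate=False)
            )
            assert set(pruned.parameter_sets) == set(naive.parameter_sets)

    def test_snoussi_never_enlarges_catalog(self, two_node_net):
        spec = parse_ctl("EF(a = 1)", two_node_net)
        base = enumerate_parameter_sets(two_node_net, spec)
        tight = enumerate_parameter_sets(
            two_node_net, spec, EnumerationOptions(snoussi=True)
        )
        assert set(tight.parameter_sets) <= set(base.parameter_sets)

    def test_cap_yields_partial_catalog(self, two_node_net):
        spec = parse_ctl("TRUE", two_node_net)
        catalog = enumerate_parameter_sets(
            two_node_net, spec, EnumerationOptions(max_candidates=5)
        )
        assert not catalog.complete
        assert catalog.candidates_checked == 5

    def test_members_reverify(self, two_node_net):
        spec = parse_ctl("AG(EF(a = 0 & b = 0))", two_node_net)
        catalog = enumerate_parameter_sets(two_node_net, spec)
        assert catalog.parameter_sets
        for ps in catalog.parameter_sets:
            assert satisfies_spec(two_node_net, ps, spec)


class TestForcedEntries:
    def test_steady_state_propagation_full_conjunction(self, two_node_net):
        # AG over a full state assignment forces both entities' K entries
        spec = parse_ctl("EF(AG(a = 1 & b = 1))", two_node_net)
        forced = forced_entries(two_node_net, spec)
        assert forced[("a", frozenset())] == 1  # b active: inhibitor not a resource
        assert forced[("b", frozenset({"a"}))] == 1
        assert len(forced) == 2

    def test_partial_conjunction_forces_only_invariant_rows(self, hif1_model):
        from qualdyn.case_study import load_ctl_formulas

        net = hif1_model.network
        f1, f2, f3 = load_ctl_formulas(net)
        forced = forced_entries(net, f2)
        # AKT, p53 and OGT have resource sets independent of the free
        # entities inside the homeostatic region
        assert forced[("AKT", frozenset())] == 1
        assert forced[("p53", frozenset())] == 0
        assert forced[("OGT", frozenset())] == 0

    def test_packaged_set_consistent_with_propagation(self, hif1_model):
        from qualdyn.case_study import ctl_conjunction

        net = hif1_model.network
        forced = forced_entries(net, ctl_conjunction(net))
        for (entity, resources), level in forced.items():
            assert hif1_model.parameters.table[entity][resources] == level


class TestParameterTable:
    def test_two_node_shape(self, two_node_net):
        spec = parse_ctl("TRUE", two_node_net)
        catalog = enumerate_parameter_sets(two_node_net, spec)
        table = parameter_table(catalog)
        assert table.shape == (4, 16)
        assert list(table.columns)[:2] == ["M1", "M2"]
        assert "K_a{}" in table.index and "K_a{b}" in table.index

    def test_single_model_catalog(self, two_node_net, two_node_model):
        catalog = enumeration.ModelCatalog(two_node_net, [two_node_model.parameters])
        table = parameter_table(catalog)
        assert table.shape == (4, 1)

    def test_empty_catalog_raises(self, two_node_net):
        with pytest.raises(ValueError):
            parameter_table(enumeration.ModelCatalog(two_node_net, []))


class TestSelectModel:
    def test_selects_by_cycle_criterion(self, two_node_net, two_node_model):
        spec = parse_ctl("TRUE", two_node_net)
        catalog = enumerate_parameter_sets(two_node_net, spec)
        cycle = [(0, 0), (1, 0), (1, 1), (0, 1)]
        model = select_model(
            catalog, SelectionCriteria(require_cycle_through=cycle)
        )
        graph = q.build_state_graph(model)
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            assert graph.graph.has_edge(a, b)

    def test_unique_deadlock_criterion(self, two_node_net):
        spec = parse_ctl("TRUE", two_node_net)
        catalog = enumerate_parameter_sets(two_node_net, spec)
        model = select_model(
            catalog, SelectionCriteria(unique_deadlock_at=(1, 1))
        )
        assert q.fixed_points(model) == [(1, 1)]

    def test_no_member_meets_criteria(self, two_node_net, two_node_model):
        catalog = enumeration.ModelCatalog(two_node_net, [two_node_model.parameters])
        with pytest.raises(NoModelMeetsCriteria) as err:
            select_model(catalog, SelectionCriteria(unique_deadlock_at=(0, 0)))
        assert "M1" in err.value.failures

    def test_singleton_catalog_meeting_criteria(self, two_node_net, two_node_model):
        catalog = enumeration.ModelCatalog(two_node_net, [two_node_model.parameters])
        cycle = [(0, 0), (1, 0), (1, 1), (0, 1)]
        model = select_model(catalog, SelectionCriteria(require_cycle_through=cycle))
        assert model.parameters == two_node_model.parameters


class TestCaseStudyMembership:
    def test_packaged_set_satisfies_its_own_specification(self, hif1_model):
        from qualdyn.case_study import ctl_conjunction

        assert satisfies_spec(
            hif1_model.network, hif1_model.parameters, ctl_conjunction(hif1_model.network)
        )
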