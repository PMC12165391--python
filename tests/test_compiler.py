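"""Expansion: bindings, round-robin matching, product states, rates, initials."""

import random
import warnings
from collections import Counter

import pytest

from metareact import (CompileError, CompileWarning, Model, Simulation, Zero,
                       compile_model, expand, match_products, u)
from metareact.compiler import applicable_bindings
from metareact.reactions import Term
from metareact.units import Quantity

from oracle import oracle_expand, random_small_model


@pytest.fixture
def tree_setup():
    m = Model()
    Age, Colored, Mortal, Location = m.base_species(
        "Age", "Colored", "Mortal", "Location")
    Age.young, Age.old
    Colored.green, Colored.yellow, Colored.brown
    Location.dense, Location.sparse
    Tree = m.species("Tree", Age * Colored * Mortal * Location)
    return m, Age, Colored, Mortal, Location, Tree


class TestBindings:
    def test_inherited_slot_binds_every_descendant(self):
        m = Model()
        Mortal = m.base_species("Mortal")
        death = Mortal >> Zero [1.0]
        A, B, C = m.new(Mortal, "A", "B", "C")
        bindings = applicable_bindings(death.reactants[0], [A, B, C])
        assert [(meta.name, s.name) for meta, s in bindings] == [
            ("A", "A"), ("B", "B"), ("C", "C")]
        reactions = expand(death, [A, B, C], Quantity(1.0))
        assert [r.label() for r in reactions] == ["A -> ", "B -> ", "C -> "]

    def test_query_slot_filters_states(self, tree_setup):
        m, Age, *_, Tree = tree_setup
        mr = Age.young >> Age.old [1 / u.h]
        bindings = applicable_bindings(Term(Tree.young), [Tree])
        assert len(bindings) == 6

    def test_empty_binding_warns_and_contributes_nothing(self):
        m = Model()
        A, B = m.base_species("A", "B")
        mr = A >> Zero [1.0]
        with pytest.warns(CompileWarning):
            assert expand(mr, [B], Quantity(1.0)) == []


class TestMatching:
    def test_cyclic_matching_of_2S1_plus_S2(self):
        m = Model()
        S1, S2 = m.base_species("S1", "S2")
        reactants = [S1, S1, S2]
        products = [S1, S1, S1, S2]
        assert match_products(reactants, products) == [0, 1, 0, 2]

    def test_replication_cycles_back_to_single_reactant(self):
        m = Model()
        T = m.base_species("T")
        assert match_products([T], [T, T]) == [0, 0]

    def test_unmatched_products_get_none(self):
        m = Model()
        A = m.base_species("A")
        assert match_products([], [A]) == [None]


class TestProductStates:
    def test_matched_product_keeps_unassigned_characteristics(self, tree_setup):
        m, Age, *_, Tree = tree_setup
        mr = Tree >> Tree + Tree.young [1 / u.h]
        reactions = expand(mr, [Tree], Quantity(1.0))
        by_reactant = {r.reactants[0][0]: r for r in reactions}
        r = by_reactant["Tree.old.green.dense"]
        assert Counter(dict(r.products)) == Counter(
            {"Tree.old.green.dense": 1, "Tree.young.green.dense": 1})

    def test_aging_only_flips_the_age_dimension(self, tree_setup):
        m, Age, *_, Tree = tree_setup
        mr = Age.young >> Age.old [1 / u.h]
        reactions = expand(mr, [Tree], Quantity(1.0))
        assert len(reactions) == 6
        for r in reactions:
            src = r.reactants[0][0]
            dst = r.products[0][0]
            assert dst == src.replace(".young", ".old")

    def test_unmatched_product_born_in_default_state(self, tree_setup):
        m, Age, Colored, *_ , Tree = tree_setup
        mr = Zero >> Tree [1 / u.h]
        reactions = expand(mr, [Tree], Quantity(1.0))
        assert len(reactions) == 1
        assert reactions[0].products == [("Tree.young.green.dense", 1)]

    def test_unmatched_unsimulated_product_is_an_error(self):
        m = Model()
        A, B = m.base_species("A", "B")
        mr = A >> A + B [1.0]
        with pytest.raises(CompileError, match="not simulated"):
            expand(mr, [A], Quantity(1.0))


class TestExpansionCounts:
    def test_sexual_reproduction_gives_144(self, tree_setup):
        *_, Tree = tree_setup
        mr = Tree + Tree >> Tree + Tree.young [lambda r1, r2: 1 / u.h]
        assert len(expand(mr, [Tree], Quantity(1.0))) == 144

    def test_death_gives_12(self, tree_setup):
        m, Age, Colored, Mortal, Location, Tree = tree_setup
        mr = Mortal >> Zero [1 / u.h]
        assert len(expand(mr, [Tree], Quantity(1.0))) == 12

    def test_slot_product_counts(self, tree_setup):
        *_, Tree = tree_setup
        mr = Tree.young + Tree.old.dense >> Tree.young [1 / u.h]
        assert len(expand(mr, [Tree], Quantity(1.0))) == 6 * 3


class TestRates:
    def test_callback_invoked_per_combination(self, tree_setup):
        *_, Tree = tree_setup
        seen = []

        def rate(r1, r2):
            seen.append((r1.species_name, r2.species_name))
            return (100 if r1(Tree.model["Location"]) == r2(Tree.model["Location"])
                    else 1) / u.year

        mr = Tree + Tree >> Tree + Tree.young [rate]
        reactions = expand(mr, [Tree], Quantity(1.0))
        assert len(seen) == 144
        same = [r for r in reactions
                if r.rate.constant > 10 / (365.25 * 86400)]
        assert len(same) == 72  # half the ordered pairs share a location

    def test_zero_rate_combinations_dropped(self, tree_setup):
        *_, Tree = tree_setup
        mr = Tree + Tree >> Tree + Tree.young [
            lambda r1, r2: (1 / u.h) if r1.has("dense") else 0]
        assert len(expand(mr, [Tree], Quantity(1.0))) == 72

    def test_expression_rate_resolves_species_names(self):
        m = Model()
        A = m.base_species("A")
        mr = A >> 2 * A [lambda r: 2 * (100 - r) * r]
        reactions = expand(mr, [A], Quantity(1.0))
        assert reactions[0].rate.render() == "((2*(100-A))*A)"


class TestInitialAmounts:
    def test_concentration_times_volume(self):
        m = Model()
        A = m.base_species("A")
        A(1 / u.ml)
        sim = Simulation(A)
        sim.volume = 1 * u.ml
        compiled = sim.compile()
        assert compiled.species[0].initial == pytest.approx(1.0)

    def test_default_completion(self, tree_setup):
        m, *_, Tree = tree_setup
        Tree(50)
        sim = Simulation(Tree)
        compiled = sim.compile()
        amounts = {s.name: s.initial for s in compiled.species}
        assert amounts["Tree.young.green.dense"] == 50
        assert sum(amounts.values()) == 50

    def test_later_assignment_overrides(self, tree_setup):
        m, *_, Tree = tree_setup
        Tree(50)
        Tree(70)
        compiled = Simulation(Tree).compile()
        assert compiled.species[0].initial == 70

    def test_unassigned_default_to_zero(self):
        m = Model()
        A = m.base_species("A")
        compiled = Simulation(A).compile()
        assert compiled.species[0].initial == 0.0


class TestCompile:
    def test_snapshot_semantics_for_phases(self):
        m = Model()
        A, B = m.base_species("A", "B")
        A >> 2 * A [1.05 / u.h]
        B >> 2 * B [1 / u.h]
        s1 = Simulation(A | B)
        A + B >> Zero [0.1 / u.h]
        s2 = Simulation(A | B)
        assert len(s1.compile().reactions) == 2
        assert len(s2.compile().reactions) == 3

    def test_empty_simulated_set_rejected(self):
        with pytest.raises(Exception):
            Simulation([])

    def test_compilation_is_byte_stable(self, tree_setup):
        m, *_, Tree = tree_setup
        Tree.old >> Tree.old + Tree.young [0.1 / u.year]
        listing1 = Simulation(Tree).compile().listing()
        listing2 = Simulation(Tree).compile().listing()
        assert listing1 == listing2

    def test_provenance_is_total(self, tree_setup):
        m, Age, *_ , Tree = tree_setup
        mr1 = Age.young >> Age.old [1 / u.h]
        mr2 = Tree >> Tree + Tree.young [1 / u.h]
        compiled = Simulation(Tree).compile()
        assert len(compiled.reactions) == 6 + 12
        for r in compiled.reactions:
            origin, states = r.provenance
            assert origin in (mr1, mr2)
            assert all(s.name in {sp.name for sp in compiled.species}
                       for s in states)


class TestOracleEquivalence:
    def _compare(self, m, mr, simulated):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CompileWarning)
            got = expand(mr, simulated, Quantity(1.0))
        expected = oracle_expand(mr, simulated)
        assert len(got) == len(expected)
        for reaction, (react_counts, prod_counts) in zip(got, expected):
            assert Counter(dict(reaction.reactants)) == react_counts
            assert Counter(dict(reaction.products)) == prod_counts

    def test_randomized_small_models_match_bruteforce(self):
        rng = random.Random(20240917)
        for _ in range(60):
            m, mr, simulated = random_small_model(rng)
            self._compare(m, mr, simulated)
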