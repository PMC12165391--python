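"""Meta-species algebra: characteristics, products, derivation, queries."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metareact import Model, ModelError


@pytest.fixture
def tree_model():
    m = Model()
    Age, Colored, Mortal, Location = m.base_species(
        "Age", "Colored", "Mortal", "Location")
    Age.young, Age.old
    Colored.green, Colored.yellow, Colored.brown
    Location.dense, Location.sparse
    Tree = m.species("Tree", Age * Colored * Mortal * Location)
    return m, Age, Colored, Mortal, Location, Tree


class TestBaseSpecies:
    def test_fresh_empty_dimensions(self):
        m = Model()
        Colored, Location = m.base_species("Colored", "Location")
        assert Colored.n_species == 1 and Location.n_species == 1
        assert Colored.own_dimension is not Location.own_dimension
        assert not Colored.ancestors

    def test_duplicate_names_rejected(self):
        m = Model()
        with pytest.raises(ModelError):
            m.base_species("A", "A")
        m.base_species("A")
        with pytest.raises(ModelError):
            m.base_species("A")


class TestCharacteristics:
    def test_three_colors_give_three_states(self):
        m = Model()
        Colored = m.base_species("Colored")
        Colored.green, Colored.yellow, Colored.brown
        assert Colored.n_species == 3
        assert [s.name for s in Colored.states()] == [
            "Colored.green", "Colored.yellow", "Colored.brown"]

    def test_first_added_is_default(self):
        m = Model()
        Age = m.base_species("Age")
        Age.young, Age.old
        assert Age.default_state().name == "Age.young"

    def test_cross_dimension_collision(self, tree_model):
        m, Age, Colored, Mortal, Location, Tree = tree_model
        with pytest.raises(ModelError, match="belongs to"):
            Location.green

    def test_new_characteristic_on_product_rejected(self, tree_model):
        *_, Tree = tree_model
        with pytest.raises(ModelError, match="non-base"):
            Tree.purple


class TestCombine:
    def test_tree_has_12_species(self, tree_model):
        *_, Tree = tree_model
        assert Tree.n_species == 12

    def test_single_part_preserves_count(self):
        m = Model()
        X = m.base_species("X")
        X.a, X.b
        Y = m.species("Y", X)
        assert Y.n_species == X.n_species == 2
        assert X in Y.ancestors

    def test_repeated_part_deduplicates_dimensions(self):
        m = Model()
        Age = m.base_species("Age")
        Age.young, Age.old
        P = m.species("P", [Age, Age])
        assert P.n_species == 2
        assert len(P.dimensions) == 1


class TestDerive:
    def test_children_share_dimensions_but_not_states(self):
        m = Model()
        Mortal, Location = m.base_species("Mortal", "Location")
        Location.c1, Location.c2
        A, B = m.new(Mortal * Location, "A", "B")
        assert A.n_species == B.n_species == 2
        assert {s.name for s in A.states()}.isdisjoint(
            s.name for s in B.states())
        assert Mortal in A.ancestors and Location in A.ancestors

    def test_single_state_child(self):
        m = Model()
        X = m.base_species("X")
        C = m.new(X, "C")
        assert C.n_species == 1 and C.states()[0].name == "C"

    def test_ancestry_is_transitively_closed(self):
        m = Model()
        X = m.base_species("X")
        Y = m.new(X, "Y")
        Z = m.new(Y, "Z")
        assert X in Z.ancestors and Y in Z.ancestors


class TestEnumeration:
    def test_lexicographic_order_and_first_state(self, tree_model):
        *_, Tree = tree_model
        states = [s.name for s in Tree.states()]
        assert len(states) == 12
        assert states[0] == "Tree.young.green.dense"
        assert states == sorted(states, key=states.index)  # deterministic
        # Age varies slowest (dimension order), Location fastest
        assert states[1] == "Tree.young.green.sparse"
        assert states[6] == "Tree.old.green.dense"

    def test_base_without_characteristics_is_one_bare_state(self):
        m = Model()
        Mortal = m.base_species("Mortal")
        assert [s.name for s in Mortal.states()] == ["Mortal"]

    def test_age_enumeration(self):
        m = Model()
        Age = m.base_species("Age")
        Age.young, Age.old
        assert [s.name for s in Age.states()] == ["Age.young", "Age.old"]


class TestQueries:
    def test_refinement_filters_enumeration(self, tree_model):
        *_, Tree = tree_model
        assert len(Tree.young.matching_states()) == 6
        assert len(Tree.young.green.matching_states()) == 2

    def test_unknown_characteristic(self, tree_model):
        *_, Tree = tree_model
        with pytest.raises(ModelError):
            Tree.young.purple

    def test_double_refinement_on_same_dimension_is_an_error(self, tree_model):
        *_, Tree = tree_model
        with pytest.raises(ModelError, match="twice"):
            Tree.young.old

    def test_c_access_equals_dot_access(self, tree_model):
        *_, Tree = tree_model
        by_c = Tree.c("green").matching_states()
        by_dot = Tree.green.matching_states()
        assert [s.name for s in by_c] == [s.name for s in by_dot]

    def test_c_access_rejects_empty_string(self, tree_model):
        *_, Tree = tree_model
        with pytest.raises(ModelError):
            Tree.c("")

    def test_query_matching_equals_brute_force_filter(self, tree_model):
        *_, Tree = tree_model
        q = Tree.old.sparse
        brute = [s for s in Tree.states()
                 if {"old", "sparse"} <= set(s.name.split("."))]
        assert [s.name for s in q.matching_states()] == [s.name for s in brute]


@settings(max_examples=40, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_state_count_is_product_of_distinct_dimension_sizes(seed):
    rng = random.Random(seed)
    m = Model()
    bases = []
    for i in range(rng.randint(1, 4)):
        b = m.base_species(f"B{i}")
        for j in range(rng.randint(0, 3)):
            b._characteristic_query(f"c{i}_{j}")
        bases.append(b)
    parts = [rng.choice(bases) for _ in range(rng.randint(1, 4))]
    P = m.species("P", parts)
    expected = 1
    for d in {id(d): d for p in parts for d in p.dimensions}.values():
        if d.characteristics:
            expected *= len(d.characteristics)
    assert P.n_species == expected == len(P.states())
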