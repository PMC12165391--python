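"""Antimony/SBML writers and the declarative model-file reader."""

import json
import math
import xml.etree.ElementTree as ET

import numpy as np
import pytest

from metareact import (Model, SchemaError, Simulation, Zero, read_model_file,
                       u, write_antimony, write_model_file, write_sbml)
from metareact.zoo import build_fixture

SBML_NS = "{http://www.sbml.org/sbml/level3/version1/core}"


class TestAntimony:
    def test_golden_demo_block(self):
        fixture = build_fixture("antimony_demo")
        text = fixture.phases[0].generate_antimony("mobspy_25681")[0]
        lines = [" ".join(l.split()) for l in text.splitlines()]
        for expected in [
            "model mobspy_25681",
            "A = 0 dimensionless",
            "B = 0 dimensionless",
            "C = 0 dimensionless",
            "_vol = 1 dimensionless",
            "reaction_0: A -> ; A * 1",
            "reaction_1: B -> ; B * 1",
            "reaction_2: C -> ; C * 1",
            "reaction_3: A + B -> C; A * B * 1 * _vol^-1",
            "reaction_4: A -> 2 A; ((2*(100-A))*A)",
            "reaction_5: B -> 2 B; ((2*(100-B))*B)",
            "reaction_6: C -> 2 C; ((2*(100-C))*C)",
            "end",
        ]:
            assert expected in lines

    def test_empty_model(self):
        m = Model()
        A = m.base_species("A")
        text = write_antimony(Simulation(A).compile(), "empty")
        assert text.splitlines() == ["model empty", "A = 0 dimensionless",
                                     "_vol = 1 dimensionless", "end"]

    def test_unimolecular_death_line(self):
        m = Model()
        A = m.base_species("A")
        A >> Zero [1]
        text = write_antimony(Simulation(A).compile())
        assert "reaction_0: A -> ; A * 1" in text

    def test_dotted_species_names_are_sanitized(self):
        m = Model()
        Age = m.base_species("Age")
        Age.young, Age.old
        Age.young >> Age.old [1]
        text = write_antimony(Simulation(Age).compile())
        assert "Age_young" in text and "Age.young" not in text


class TestSbml:
    def test_structure_counts_for_annihilation_phase_two(self):
        fixture = build_fixture("annihilation")
        compiled = fixture.phases[1].compile()
        root = ET.fromstring(write_sbml(compiled))
        assert len(root.findall(f".//{SBML_NS}species")) == 2
        assert len(root.findall(f".//{SBML_NS}reaction")) == 3
        assert len(root.findall(f".//{SBML_NS}compartment")) == 1
        for rx in root.findall(f".//{SBML_NS}reaction"):
            assert rx.find(f"{SBML_NS}kineticLaw") is not None

    def test_time_event_exported(self):
        m = Model()
        A = m.base_species("A")
        s = Simulation(A)
        s.duration = 2 * u.h
        s.event_time(1 * u.h, {A: 5})
        root = ET.fromstring(write_sbml(s.compile()))
        events = root.findall(f".//{SBML_NS}event")
        assert len(events) == 1
        assert events[0].find(f"{SBML_NS}trigger") is not None

    def test_tree_model_has_12_species(self):
        compiled = build_fixture("tree").compile()
        root = ET.fromstring(write_sbml(compiled))
        assert len(root.findall(f".//{SBML_NS}species")) == 12


@pytest.fixture
def tree_doc(tmp_path):
    doc = {
        "name": "tree",
        "base_species": [
            {"name": "Age", "characteristics": ["young", "old"]},
            {"name": "Colored",
             "characteristics": ["green", "yellow", "brown"]},
            {"name": "Mortal"},
            {"name": "Location", "characteristics": ["dense", "sparse"]},
        ],
        "combined": [{"name": "Tree",
                      "parts": ["Age", "Colored", "Mortal", "Location"]}],
        "reactions": [
            {"reactants": ["Age.young"], "products": ["Age.old"],
             "rate": "1/(10*year)"},
            {"reactants": ["Mortal"], "products": ["Zero"],
             "rate": "0.05/year"},
        ],
        "initial": [{"species": "Tree.dense", "amount": 30}],
        "simulations": [{"species": ["Tree"], "duration": "30 year"}],
    }
    path = tmp_path / "tree.json"
    path.write_text(json.dumps(doc))
    return path


class TestModelFile:
    def test_tree_file_compiles_like_the_builder(self, tree_doc):
        model, chained = read_model_file(tree_doc)
        compiled = chained.phases[0].compile()
        assert len(compiled.species) == 12
        assert len(compiled.reactions) == 6 + 12
        assert compiled.species_index["Tree.young.green.dense"] == 0

    def test_unknown_characteristic_is_a_schema_error(self, tmp_path):
        doc = {"base_species": [{"name": "Age",
                                 "characteristics": ["young", "old"]}],
               "reactions": [{"reactants": ["Age.purple"],
                              "products": ["Age.old"], "rate": 1}]}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError):
            read_model_file(path)

    def test_write_read_round_trip_is_identity_on_compiled_models(
            self, tree_doc, tmp_path):
        model, chained = read_model_file(tree_doc)
        out = tmp_path / "roundtrip.yaml"
        write_model_file(model, chained, out, name="tree")
        model2, chained2 = read_model_file(out)
        first = [p.compile().listing() for p in chained.phases]
        second = [p.compile().listing() for p in chained2.phases]
        assert first == second

    def test_phase_local_reactions_follow_snapshot_semantics(self, tmp_path):
        doc = {
            "base_species": [{"name": "A"}, {"name": "B"}],
            "reactions": [
                {"reactants": ["A"], "products": ["2*A"], "rate": "1.05/h"},
                {"reactants": ["B"], "products": ["2*B"], "rate": "1/h"}],
            "initial": [{"species": "A", "amount": "1/ml"},
                        {"species": "B", "amount": "1/ml"}],
            "simulations": [
                {"species": ["A", "B"], "duration": "3 h", "volume": "1 ml"},
                {"species": ["A", "B"],
                 "duration": {"condition": "A <= 0 or B <= 0"},
                 "method": "stochastic", "volume": "1 ml", "runs": 3,
                 "seed": 2, "condition_cap": "500 h",
                 "reactions": [{"reactants": ["A", "B"], "products": ["Zero"],
                                "rate": "0.1/h"}]}],
        }
        path = tmp_path / "annih.json"
        path.write_text(json.dumps(doc))
        model, chained = read_model_file(path)
        assert len(chained.phases[0].compile().reactions) == 2
        assert len(chained.phases[1].compile().reactions) == 3
        res = chained.run(seed=1)
        assert len(res) == 3
        finals = np.array([res.final("A"), res.final("B")])
        assert np.all(np.min(finals, axis=0) == 0)

    def test_expression_rate_from_file(self, tmp_path):
        doc = {
            "base_species": [{"name": "A"}],
            "reactions": [{"reactants": ["A"], "products": ["2*A"],
                           "rate": {"expression": "2*(100-r1)*r1"}}],
            "initial": [{"species": "A", "amount": 1}],
            "simulations": [{"species": ["A"], "duration": 1}],
        }
        path = tmp_path / "expr.json"
        path.write_text(json.dumps(doc))
        model, chained = read_model_file(path)
        compiled = chained.phases[0].compile()
        assert compiled.reactions[0].rate.render() == "((2*(100-A))*A)"
        res = chained.run()
        assert res["A"][0][-1] == pytest.approx(100.0, rel=1e-3)

    def test_antimony_output_matches_internal_ode(self, tmp_path):
        # the exported rate strings, evaluated literally, must reproduce the
        # solver's dynamics (independent re-integration from the export text)
        fixture = build_fixture("antimony_demo")
        compiled = fixture.phases[0].compile()
        text = write_antimony(compiled)
        rates = {}
        inits = {}
        for line in text.splitlines():
            line = line.strip()
            if line.startswith("reaction_"):
                head, rate = line.split(";")
                name, arrow = head.split(":")
                rates[name.strip()] = (arrow.strip(), rate.strip())
            elif "= " in line and line.endswith("dimensionless"):
                key = line.split("=")[0].strip()
                inits[key] = float(line.split("=")[1].split()[0])
        from scipy.integrate import solve_ivp
        names = [s.name for s in compiled.species]
        inits["A"] = 5.0  # start away from zero so dynamics are nontrivial

        def parse_side(side):
            out = []
            for token in side.split("+"):
                token = token.strip()
                if not token:
                    continue
                if " " in token:
                    n, sp = token.split()
                    out.append((sp, int(n)))
                else:
                    out.append((token, 1))
            return out

        def f(t, y):
            env = dict(zip(names, y))
            env["_vol"] = inits["_vol"]
            dy = dict.fromkeys(names, 0.0)
            for name, (arrow, rate) in rates.items():
                lhs, rhs = arrow.split("->")
                v = eval(rate.replace("^", "**"), {}, env)
                for sp, n in parse_side(lhs):
                    dy[sp] -= n * v
                for sp, n in parse_side(rhs):
                    dy[sp] += n * v
            return [dy[n] for n in names]

        y0 = [inits.get(n, 0.0) for n in names]
        sol = solve_ivp(f, (0, 1.0), y0, rtol=1e-8, atol=1e-10)

        model = fixture.model
        model._initials.append((fixture.species["A"]._as_query(), 5.0))
        sim = Simulation([fixture.species[k] for k in ("A", "B", "C")], model)
        sim._reactions = fixture.phases[0]._reactions
        sim.duration = 1.0
        sim.rtol, sim.atol = 1e-8, 1e-10
        res = sim.run()
        for i, n in enumerate(names):
            ours = res[n][0][-1]
            theirs = sol.y[i][-1]
            assert abs(ours - theirs) <= 1e-4 * max(1.0, abs(theirs))
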