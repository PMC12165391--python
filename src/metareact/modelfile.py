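"""Declarative model files (JSON or YAML).

The schema mirrors the builder API one-to-one, so reading a file yields the
same compiled models as the equivalent builder calls:

.. code-block:: yaml

    name: demo
    base_species:
      - {name: Age, characteristics: [young, old]}
      - {name: Mortal}
    combined:
      - {name: Tree, parts: [Age, Colored, Mortal, Location]}
    derived:
      - {parent: "Replicator*Mortal", names: [A, B, C]}
    parameters:
      - {name: k1, values: [1, 2, 3]}
    reactions:
      - {reactants: ["Age.young"], products: ["Age.old"], rate: "1/(10*year)"}
      - {reactants: ["Mortal"], products: ["Zero"], rate: 1}
      - {reactants: ["A"], products: ["2*A"], rate: {expression: "2*(100-r1)*r1"}}
    initial:
      - {species: "A", amount: "1/ml"}
    simulations:
      - species: [A, B]
        duration: "3 h"                     # or {condition: "A <= 0 or B <= 0"}
        method: deterministic
        volume: "1 ml"
        runs: 1
        seed: 0
        reactions: []                       # declared before this phase's snapshot
        events:
          - {time: "25 h", set: {A: 100}}
          - {condition: "A > 50", set: {B: 0}}

Rate strings are quantity expressions (the unit grammar); rate expressions
reference reactant slots as ``r1``, ``r2``, ... and may use declared
parameter names.  Amounts are counts (numbers) or concentration/count
quantity strings.  Reactions listed inside a simulation entry are declared
immediately before that phase is constructed, which is how multi-phase
protocols add reactions between snapshots.
"""

from __future__ import annotations

import json
import re

from .errors import SchemaError
from .expressions import (BinOp, Num, ParamRef, Pow, RateExpression, SlotRef,
                          SpeciesRef)
from .model import Condition, MetaSpecies, Model, Parameter, Query
from .reactions import MetaReaction, Term, declare_reaction
from .simulation import ChainedSimulation, Simulation
from .units import Quantity, UnitDim, parse_quantity

# ---------------------------------------------------------------------------
# small parsers
# ---------------------------------------------------------------------------


def _parse_term(text: str, model: Model) -> Term | None:
    s = str(text).strip()
    if s == "Zero":
        return None
    mult = 1
    m = re.match(r"^(\d+)\s*\*?\s*(.+)$", s)
    if m:
        mult = int(m.group(1))
        s = m.group(2).strip()
    parts = s.split(".")
    name = parts[0]
    if name not in model:
        raise SchemaError(f"unknown meta-species {name!r} in term {text!r}")
    query = model[name]._as_query()
    for char in parts[1:]:
        query = query._refine(char)
    return Term(query, mult)


_EXPR_TOKEN = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?)|(?P<ident>[A-Za-z_][A-Za-z_0-9.]*)"
    r"|(?P<op>\*\*|\^|[-+*/()]))")


def parse_expression(text: str, model: Model) -> RateExpression:
    """Parse an arithmetic rate expression over r1..rn and parameter names."""
    tokens = []
    pos = 0
    s = str(text)
    while pos < len(s):
        m = _EXPR_TOKEN.match(s, pos)
        if m is None:
            if s[pos:].strip() == "":
                break
            raise SchemaError(f"cannot parse expression {text!r} at {s[pos:]!r}")
        pos = m.end()
        tokens.append((m.lastgroup, m.group(m.lastgroup)))
    tokens.append(("end", ""))
    idx = 0

    def peek():
        return tokens[idx]

    def take():
        nonlocal idx
        tok = tokens[idx]
        idx += 1
        return tok

    def atom() -> RateExpression:
        kind, v = take()
        if kind == "num":
            return Num(float(v))
        if kind == "ident":
            m = re.fullmatch(r"r(\d+)", v)
            if m:
                return SlotRef(int(m.group(1)) - 1)
            if v in model._parameters:
                return ParamRef(model._parameters[v])
            raise SchemaError(f"unknown name {v!r} in expression {text!r} "
                              f"(reactants are r1..rn; parameters must be declared)")
        if (kind, v) == ("op", "("):
            e = addsub()
            if take() != ("op", ")"):
                raise SchemaError(f"unbalanced parentheses in {text!r}")
            return e
        if (kind, v) == ("op", "-"):
            return Num(0.0) - atom()
        raise SchemaError(f"cannot parse expression {text!r} near {v!r}")

    def power() -> RateExpression:
        base = atom()
        if peek() in (("op", "**"), ("op", "^")):
            take()
            exp = atom()
            if not isinstance(exp, Num) or not float(exp.value).is_integer():
                raise SchemaError(f"exponents must be integer literals in {text!r}")
            return Pow(base, int(exp.value))
        return base

    def muldiv() -> RateExpression:
        e = power()
        while peek() in (("op", "*"), ("op", "/")):
            _, op = take()
            e = BinOp(op, e, power())
        return e

    def addsub() -> RateExpression:
        e = muldiv()
        while peek() in (("op", "+"), ("op", "-")):
            _, op = take()
            e = BinOp(op, e, muldiv())
        return e

    result = addsub()
    if peek()[0] != "end":
        raise SchemaError(f"trailing input in expression {text!r}")
    return result


_CMP_RE = re.compile(r"^\s*([A-Za-z_][A-Za-z_0-9.]*)\s*(<=|>=|<|>|==?)\s*"
                     r"([-+0-9.eE]+)\s*$")


def parse_condition(text: str, model: Model) -> Condition:
    """Parse a boolean condition over species amounts ('A <= 0 or B <= 0')."""
    s = str(text)

    def split_top(s: str, seps: tuple[str, ...]):
        depth = 0
        i = 0
        while i < len(s):
            ch = s[i]
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            elif depth == 0:
                for sep in seps:
                    end = i + len(sep)
                    if s[i:end].lower() == sep:
                        before, after = s[:i], s[end:]
                        if sep in ("or", "and"):
                            if (i == 0 or s[i - 1].isalnum()
                                    or (end < len(s) and s[end].isalnum())):
                                continue
                        return before, after
            i += 1
        return None

    for seps, kind in ((("or", "|"), "or"), (("and", "&"), "and")):
        parts = split_top(s, seps)
        if parts:
            return Condition(kind, (parse_condition(parts[0], model),
                                    parse_condition(parts[1], model)))
    s = s.strip()
    if s.startswith("(") and s.endswith(")"):
        depth = 0
        for i, ch in enumerate(s):
            depth += ch == "("
            depth -= ch == ")"
            if depth == 0 and i < len(s) - 1:
                break
        else:
            return parse_condition(s[1:-1], model)
    m = _CMP_RE.match(s)
    if not m:
        raise SchemaError(f"cannot parse condition {text!r}")
    path, op, value = m.groups()
    op = "==" if op == "=" else op
    term = _parse_term(path, model)
    query = term.query
    payload_op = {"==": "=="}.get(op, op)
    return Condition("cmp", (payload_op, query, float(value)))


def _parse_rate(spec, model: Model):
    if isinstance(spec, dict):
        if "expression" not in spec:
            raise SchemaError(f"rate object must have an 'expression' key: {spec!r}")
        return parse_expression(spec["expression"], model)
    if isinstance(spec, (int, float)):
        return float(spec)
    if isinstance(spec, str):
        if spec in model._parameters:
            return model._parameters[spec]
        return parse_quantity(spec)
    raise SchemaError(f"cannot interpret rate {spec!r}")


def _parse_amount(spec):
    if isinstance(spec, (int, float)):
        return float(spec)
    return parse_quantity(spec)


# ---------------------------------------------------------------------------
# reader
# ---------------------------------------------------------------------------


def _load_document(path) -> dict:
    text = open(path).read()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        doc = yaml.safe_load(text)
    else:
        try:
            doc = json.loads(text)
        except json.JSONDecodeError:
            import yaml
            doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError(f"model file {path} does not contain a mapping")
    return doc


def _declare_reactions(entries, model: Model):
    for entry in entries or []:
        try:
            reactants = [t for r in entry.get("reactants", [])
                         if (t := _parse_term(r, model)) is not None]
            products = [t for p in entry.get("products", [])
                        if (t := _parse_term(p, model)) is not None]
            rate = _parse_rate(entry.get("rate"), model) \
                if entry.get("rate") is not None else None
            declare_reaction(reactants, products, rate)
        except SchemaError:
            raise
        except Exception as exc:
            raise SchemaError(f"invalid reaction entry {entry!r}: {exc}") from exc


def read_model_file(path):
    """Build a registry and simulation phases from a declarative model file.

    Returns ``(model, chained_simulation_or_None)``.
    """
    doc = _load_document(path)
    model = Model()

    for entry in doc.get("base_species", []) or []:
        name = entry["name"] if isinstance(entry, dict) else str(entry)
        ms = model.base_species(name)
        chars = entry.get("characteristics", []) if isinstance(entry, dict) else []
        for c in chars:
            ms._characteristic_query(c)

    for entry in doc.get("combined", []) or []:
        parts = []
        for pname in entry["parts"]:
            if pname not in model:
                raise SchemaError(f"unknown part {pname!r} in combined species "
                                  f"{entry['name']!r}")
            parts.append(model[pname])
        model.species(entry["name"], parts)

    for entry in doc.get("derived", []) or []:
        parent_expr = entry["parent"]
        part_names = [p.strip() for p in str(parent_expr).split("*")]
        for pname in part_names:
            if pname not in model:
                raise SchemaError(f"unknown parent {pname!r} in derived entry")
        parent = model[part_names[0]]
        for pname in part_names[1:]:
            parent = parent * model[pname]
        model.new(parent, *entry["names"])

    for entry in doc.get("parameters", []) or []:
        model.parameter(entry["name"], entry.get("values", entry.get("value")))

    _declare_reactions(doc.get("reactions"), model)

    for entry in doc.get("initial", []) or []:
        term = _parse_term(entry["species"], model)
        model.set_initial(term.query, _parse_amount(entry["amount"]))

    phases = []
    for entry in doc.get("simulations", []) or []:
        _declare_reactions(entry.get("reactions"), model)
        members = []
        for name in entry.get("species", []):
            if name not in model:
                raise SchemaError(f"unknown simulated species {name!r}")
            members.append(model[name])
        if not members:
            raise SchemaError("a simulation entry needs a 'species' list")
        sim = Simulation(members, model)
        duration = entry.get("duration")
        if isinstance(duration, dict):
            sim.duration = parse_condition(duration["condition"], model)
        elif duration is not None:
            sim.duration = _parse_amount(duration)
        sim.method = entry.get("method", "deterministic")
        if sim.method not in ("deterministic", "stochastic"):
            raise SchemaError(f"unknown method {sim.method!r}")
        if "volume" in entry:
            sim.volume = _parse_amount(entry["volume"])
        sim.runs = int(entry.get("runs", 1))
        sim.seed = int(entry.get("seed", 0))
        sim.output_points = int(entry.get("output_points", 250))
        if "condition_cap" in entry:
            sim.condition_cap = _parse_amount(entry["condition_cap"])
        for ev in entry.get("events", []) or []:
            assignments = []
            for target, value in (ev.get("set") or {}).items():
                term = _parse_term(target, model)
                assignments.append((term.query, _parse_amount(value)))
            if "time" in ev:
                sim.event_time(_parse_amount(ev["time"]), assignments,
                               label=ev.get("label", ""))
            elif "condition" in ev:
                sim.event_condition(parse_condition(ev["condition"], model),
                                    assignments, label=ev.get("label", ""))
            else:
                raise SchemaError(f"event needs a 'time' or 'condition': {ev!r}")
        phases.append(sim)

    chained = ChainedSimulation(phases) if phases else None
    return model, chained


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------


def _quantity_string(q) -> str | float:
    if isinstance(q, (int, float)):
        return float(q)
    c = q.to_canonical()
    if c.dim.dimensionless:
        return c.magnitude
    num, den = [], []
    for sym, exp in (("s", c.dim.time), ("L", c.dim.volume),
                     ("count", c.dim.substance)):
        if exp > 0:
            num.append(sym if exp == 1 else f"{sym}**{exp}")
        elif exp < 0:
            den.append(sym if exp == -1 else f"{sym}**{-exp}")
    out = repr(c.magnitude)
    if num:
        out += "*" + "*".join(num)
    for d in den:
        out += "/" + d
    return out


def _term_string(term: Term) -> str:
    label = term.query.label
    return label if term.multiplicity == 1 else f"{term.multiplicity}*{label}"


def _rate_spec(rate, where: str):
    if isinstance(rate, (int, float)):
        return float(rate)
    if isinstance(rate, Quantity):
        return _quantity_string(rate)
    if isinstance(rate, Parameter):
        return rate.name
    if isinstance(rate, RateExpression):
        from .expressions import Piecewise
        if any(isinstance(n, Piecewise) for n in _walk(rate)):
            raise SchemaError(f"piecewise rate in {where} is not serializable")
        return {"expression": rate.render()}
    raise SchemaError(f"rate of {where} is a Python callback and cannot be "
                      f"serialized to a model file")


def _walk(node):
    yield node
    for attr in ("left", "right", "base", "condition", "if_true", "if_false"):
        child = getattr(node, attr, None)
        if isinstance(child, RateExpression):
            yield from _walk(child)


def _condition_string(cond: Condition) -> str:
    if cond.kind == "cmp":
        op, query, value = cond.payload
        v = value.canonical_magnitude if isinstance(value, Quantity) else value
        return f"{query.label} {op} {v}"
    a, b = cond.payload
    joiner = " or " if cond.kind == "or" else " and "
    return f"({_condition_string(a)}){joiner}({_condition_string(b)})"


def write_model_file(model: Model, phases=None, path=None, name: str = "model"):
    """Serialize a registry (and optional phases) to the declarative schema.

    Returns the document; writes YAML or JSON to ``path`` if given.  Rates
    given as Python callbacks are not serializable and raise ``SchemaError``.
    """
    doc: dict = {"name": name}
    base, combined, derived = [], [], []
    for ms in model._species.values():
        kind, parts = ms.construction
        if kind == "base":
            base.append({"name": ms.name,
                         "characteristics": [c.name for c in
                                             ms.own_dimension.characteristics]})
        elif kind == "combined":
            combined.append({"name": ms.name, "parts": parts})
        else:
            derived.append({"parent": "*".join(parts), "names": [ms.name]})
    if base:
        doc["base_species"] = base
    if combined:
        doc["combined"] = combined
    if derived:
        doc["derived"] = _merge_derived(derived)
    if model._parameters:
        doc["parameters"] = [{"name": p.name,
                              "values": [(_quantity_string(v)
                                          if isinstance(v, Quantity) else v)
                                         for v in p.values]}
                             for p in model._parameters.values()]

    phase_list = phases.phases if isinstance(phases, ChainedSimulation) \
        else list(phases or [])
    cutoffs = [len(p._reactions) for p in phase_list]
    top_n = min(cutoffs) if cutoffs else len(model._reactions)

    def reaction_entry(mr: MetaReaction) -> dict:
        return {"reactants": [_term_string(t) for t in mr.reactants] or ["Zero"],
                "products": [_term_string(t) for t in mr.products] or ["Zero"],
                "rate": _rate_spec(mr.rate, mr.label())}

    doc["reactions"] = [reaction_entry(mr) for mr in model._reactions[:top_n]]
    if model._initials:
        doc["initial"] = [{"species": (q._as_query() if isinstance(q, MetaSpecies)
                                       else q).label,
                           "amount": _quantity_string(a)}
                          for q, a in model._initials]

    sims = []
    declared = top_n
    for p in phase_list:
        entry: dict = {"species": [m.name for m in p.simulated]}
        if len(p._reactions) > declared:
            entry["reactions"] = [reaction_entry(mr)
                                  for mr in p._reactions[declared:]]
            declared = len(p._reactions)
        if isinstance(p.duration, Condition):
            entry["duration"] = {"condition": _condition_string(p.duration)}
        elif p.duration is not None:
            entry["duration"] = _quantity_string(p.duration)
        entry["method"] = p.method
        entry["volume"] = _quantity_string(p.volume)
        if p.runs != 1:
            entry["runs"] = p.runs
        if p.seed:
            entry["seed"] = p.seed
        if p.output_points != 250:
            entry["output_points"] = p.output_points
        if p.events:
            evs = []
            for ev in p.events:
                e: dict = {"set": {(t._as_query() if isinstance(t, MetaSpecies)
                                    else t).label: _quantity_string(v)
                                   for t, v in ev.assignments}}
                if ev.time is not None:
                    e = {"time": _quantity_string(ev.time), **e}
                else:
                    e = {"condition": _condition_string(ev.condition), **e}
                evs.append(e)
            entry["events"] = evs
        sims.append(entry)
    if sims:
        doc["simulations"] = sims

    if path is not None:
        with open(path, "w") as fh:
            if str(path).endswith((".yaml", ".yml")):
                import yaml
                yaml.safe_dump(doc, fh, sort_keys=False)
            else:
                json.dump(doc, fh, indent=2)
    return doc


def _merge_derived(entries: list[dict]) -> list[dict]:
    merged: dict[str, list[str]] = {}
    for e in entries:
        merged.setdefault(e["parent"], []).extend(e["names"])
    return [{"parent": parent, "names": names} for parent, names in merged.items()]
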