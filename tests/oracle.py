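"""Brute-force expansion oracle, independent of the compiler.

Literally enumerates all reactant state tuples with nested loops, applies the
cyclic product-matching rule step by step, and derives product states by
copying the matched state's characteristic assignment.  Used to cross-check
``metareact.expand`` on randomized small models.
"""

import itertools
import random
from collections import Counter

from metareact.model import Model, SpeciesState


def oracle_expand(meta_reaction, simulated):
    """Return [(reactant multiset, product multiset)] per ordered binding tuple."""
    slots = []
    for term in meta_reaction.reactants:
        slots.extend([term] * term.multiplicity)
    product_slots = []
    for term in meta_reaction.products:
        product_slots.extend([term] * term.multiplicity)

    options = []
    for term in slots:
        opts = []
        for meta in simulated:
            if term.query.meta is meta or term.query.meta in meta.ancestors:
                for state in meta.states():
                    if all(state.assignment.get(dim) is char
                           for dim, char in term.query.constraints.items()):
                        opts.append(state)
        options.append(opts)
    if any(not o for o in options):
        return []

    results = []
    for combo in itertools.product(*options):
        slot_metas = [t.query.meta for t in slots]
        last = {}
        assignments = []
        for pt in product_slots:
            target = pt.query.meta
            found = None
            if slot_metas:
                start = last.get(id(target), -1) + 1
                for step in range(len(slot_metas)):
                    j = (start + step) % len(slot_metas)
                    if slot_metas[j] is target:
                        found = j
                        break
            if found is not None:
                last[id(target)] = found
                base = dict(combo[found].assignment)
                meta = combo[found].meta
            else:
                meta = target
                base = {d: d.default for d in meta.dimensions
                        if d.characteristics}
            for dim, char in pt.query.constraints.items():
                base[dim] = char
            assignments.append(SpeciesState(meta, base).name)
        results.append((Counter(s.name for s in combo), Counter(assignments)))
    return results


def random_small_model(rng: random.Random):
    """A random registry with <=3 meta-species, <=3 dims, <=3 characteristics,
    one random meta-reaction, and a simulated subset."""
    m = Model()
    n_base = rng.randint(1, 3)
    bases = []
    for i in range(n_base):
        b = m.base_species(f"B{i}")
        for j in range(rng.randint(0, 3)):
            b._characteristic_query(f"c{i}_{j}")
        bases.append(b)

    metas = list(bases)
    if rng.random() < 0.6 and len(bases) > 1:
        k = rng.randint(2, len(bases))
        parts = rng.sample(bases, k)
        metas.append(m.species("P", parts))
    if rng.random() < 0.4:
        parent = rng.choice(metas)
        metas.extend(m.new(parent, "D0", "D1") if rng.random() < 0.5
                     else [m.new(parent, "D0")])

    simulated = [ms for ms in metas if rng.random() < 0.7] or [rng.choice(metas)]

    def random_term(pool):
        meta = rng.choice(pool)
        query = meta._as_query()
        candidates = [d for d in meta.dimensions if d.characteristics]
        if candidates and rng.random() < 0.6:
            dim = rng.choice(candidates)
            query = query._refine(rng.choice(dim.characteristics).name)
        from metareact.reactions import Term
        return Term(query, rng.randint(1, 2))

    n_react = rng.randint(0, 2)
    reactants = [random_term(metas) for _ in range(n_react)]
    # products must be matchable or simulated (unmatched products are born)
    reactant_metas = [t.query.meta for t in reactants]
    product_pool = list(dict.fromkeys(reactant_metas + simulated))
    products = [random_term(product_pool) for _ in range(rng.randint(0, 2))]
    if not reactants and not products:
        products = [random_term(simulated)]

    from metareact.reactions import declare_reaction
    mr = declare_reaction(reactants, products, 1.0)
    return m, mr, simulated
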