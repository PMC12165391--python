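# metareact

A meta-species language for biochemical reaction networks (BCRNs), for
modelers who find that realistic models explode into dozens of near-identical
species and reactions.  Instead of writing every reaction out by hand, you
compose *base species* that each contribute one axis of discrete
*characteristics* (young/old, green/yellow/brown, dense/sparse, ...) into
product meta-species whose concrete species are the Cartesian product of
those axes — and whose reactions are inherited from every ancestor.  A
single *meta-reaction* then compiles into the whole family of concrete
reactions it stands for.

## The model

A meta-species `M` with dimensions `D_1, ..., D_k` (each an ordered list of
characteristics) denotes the species set

```
species(M) = { M.c_1.c_2...c_k : c_i ∈ D_i, D_i non-empty }
```

In a reactant, a dot is a **query**: `Tree.young` is the set of all `Tree`
species whose Age component is `young`.  In a product, a dot is an
**assignment**: the product `Tree.young` is "the matched reactant, with Age
set to young".  Products are paired with reactants by a deterministic cyclic
round-robin over slots of the same meta-species, which is what makes
reproduction-style reactions (`R >> 2*R`) well-defined without enumerating
states.  A meta-reaction with unit reactant slots matching `n_1, ..., n_k`
concrete states expands into `n_1 × ... × n_k` concrete reactions (ordered
tuples, no symmetric merging).

Rates are mass-action by default — deterministic rate
`k · V^-(n-1) · Π x_i`, stochastic propensity with falling factorials
`k · V^-(n-1) · Π x(x-1).../n!` — or arbitrary expressions over reactant
amounts, written as Python callbacks that receive one state handle per
reactant slot.  Quantities carry units over the (time, volume, substance)
axes; rate constants are dimension-checked against the reaction order and
converted to a canonical (second, liter, count) basis before simulation.

## A worked example

```python
from metareact import Model, Simulation, Zero, u

m = Model()
Age, Colored, Mortal, Location = m.base_species(
    "Age", "Colored", "Mortal", "Location")

Age.young >> Age.old [1 / (10 * u.year)]       # aging
Colored.green, Colored.yellow, Colored.brown   # leaf colors
Location.dense, Location.sparse                # habitats
Mortal >> Zero [0.05 / u.year]                 # death

Tree = m.species("Tree", Age * Colored * Mortal * Location)

def reproduction(r1, r2):                      # state-dependent rate
    same = r1(Location) == r2(Location) and r1(Colored) == r2(Colored)
    return (100 if same else 1) / u.year

Tree + Tree >> Tree + Tree.young [reproduction]

Tree.dense(30)                                 # initial counts
sim = Simulation(Tree)
sim.duration = 30 * u.year
compiled = sim.compile()
print(len(compiled.species), "species,", len(compiled.reactions), "reactions")
```

This prints `12 species, 162 reactions`: the Tree meta-species spans
2 (Age) × 3 (Colored) × 2 (Location) = 12 concrete species, the aging
meta-reaction expands to 6 reactions, death to 12, and the two-parent
reproduction to 12 × 12 = 144.  Running `sim.run()` returns a result set
queryable without declared observables — `results[Tree.young]` sums the six
young species.

The `examples/` directory has one short script per capability: the tree
model, the two-phase deterministic→stochastic annihilation protocol with a
condition-based stop (`(A <= 0) | (B <= 0)`), the event-driven bistable
inflammation detector, the quorum-sensing lysis oscillator, a factorial
parameter sweep over a distributed XOR gate, Antimony/SBML export, and the
declarative YAML/JSON model-file schema.  A thin CLI wraps the file-based
workflows: `metareact compile|simulate|validate|demo`.

## Layout

```
src/metareact/     model.py (meta-species algebra), reactions.py (DSL),
                   units.py, expressions.py, compiler.py, simulation.py,
                   results.py, antimony.py, sbml.py, modelfile.py, zoo.py,
                   cli.py
tests/             pytest suite incl. a brute-force expansion oracle
examples/          one narrative script per capability
docs/methods.md    models, conventions, numerical choices, limitations
```
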