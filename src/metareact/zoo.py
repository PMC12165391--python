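"""Fixture builders for the showcase models.

Each builder assembles a registry and simulation phases with the builder API
and returns a :class:`Fixture`.  Where a published description fixes only the
qualitative behavior, rate constants are stand-ins chosen to realize that
behavior; every stand-in is called out in the builder's docstring.  Building
a fixture twice yields structurally identical compiled models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ModelError
from .model import Model
from .reactions import Zero
from .simulation import ChainedSimulation, Simulation
from .units import u


@dataclass
class Fixture:
    name: str
    model: Model
    phases: list[Simulation]
    species: dict = field(default_factory=dict)
    notes: str = ""

    @property
    def chained(self) -> ChainedSimulation:
        return ChainedSimulation(self.phases)

    def compile(self):
        return self.phases[0].compile()


def tree() -> Fixture:
    """Two-location tree population: aging, death, competition, replication,
    color cycling and sexual reproduction over a 12-state meta-species.

    The aging, death, competition and replication constants and the initial
    counts are stand-ins (the published description fixes the reaction
    structure, not these numbers).  The reproduction rate is 100/year when
    both parents share location and color, 1/year otherwise.
    """
    m = Model()
    Age, Colored, Mortal, Location = m.base_species(
        "Age", "Colored", "Mortal", "Location")

    Age.young >> Age.old [1 / (10 * u.year)]

    Colored.green, Colored.yellow, Colored.brown
    Location.dense, Location.sparse

    Mortal >> Zero [0.05 / u.year]

    Tree = m.species("Tree", Age * Colored * Mortal * Location)

    # old trees suppress young ones in the dense location (matching keeps the
    # old tree); old trees replicate into a young copy of themselves
    Tree.dense.old + Tree.dense.young >> Tree.dense.old [1e-3 / u.year]
    Tree.old >> Tree.old + Tree.young [0.1 / u.year]

    def reproduction_rate(r1, r2):
        if r1(Location) == r2(Location) and r1(Colored) == r2(Colored):
            return 100 / u.year
        return 1 / u.year

    Tree + Tree >> Tree + Tree.young [reproduction_rate]

    colors = ["green", "yellow", "brown"]
    for color, next_color in zip(colors, colors[1:] + colors[:1]):
        Tree.c(color) >> Tree.c(next_color) [10 / u.year]

    Tree.dense(30)
    Tree.sparse(30)

    sim = Simulation(Tree)
    sim.duration = 30 * u.year
    return Fixture("tree", m, [sim], {"Tree": Tree, "Age": Age,
                                      "Colored": Colored, "Mortal": Mortal,
                                      "Location": Location})


def annihilation() -> Fixture:
    """Signal reconstruction by mutual annihilation of two replicating species.

    Phase 1 grows A and B deterministically for 3 h (replication only);
    phase 2 adds the annihilation reaction and runs stochastically until one
    species is exhausted.  All rates and initial concentrations are the
    published ones.
    """
    m = Model()
    A, B = m.base_species("A", "B")

    A >> 2 * A [1.05 / u.h]
    B >> 2 * B [1 / u.h]

    A(1 / u.ml)
    B(1 / u.ml)

    s1 = Simulation(A | B)
    s1.duration = 3 * u.h
    s1.volume = 1 * u.ml

    A + B >> Zero [0.1 / u.h]

    s2 = Simulation(A | B)
    s2.duration = (A <= 0) | (B <= 0)
    s2.method = "stochastic"
    s2.volume = 1 * u.ml
    s2.condition_cap = 500 * u.h

    return Fixture("annihilation", m, [s1, s2], {"A": A, "B": B})


def antimony_demo() -> Fixture:
    """Replicating, mortal species A, B, C with a combination reaction;
    the canonical text-export demonstration model.

    Replication uses the saturating expression rate 2*(100 - x)*x; all other
    rates are the unit constants of the original listing.
    """
    m = Model()
    Replicator, Mortal = m.base_species("Replicator", "Mortal")
    A, B, C = m.new(Replicator * Mortal, "A", "B", "C")

    Mortal >> Zero [1]
    A + B >> C [1]
    Replicator >> 2 * Replicator [lambda r: 2 * (100 - r) * r]

    sim = Simulation(A | B | C)
    sim.duration = 10.0
    return Fixture("antimony_demo", m, [sim],
                   {"A": A, "B": B, "C": C, "Replicator": Replicator,
                    "Mortal": Mortal})


def detector() -> Fixture:
    """Bistable gut-inflammation detector: a TTR-triggered phospho-relay
    feeding a Cro/CI mutual-repression toggle.

    The phosphorylation/dephosphorylation constants (5e-3/s) and the
    phospho-driven Cro production (1/min) are the published ones; the toggle
    (production 20/h, repression threshold 20 counts, Hill coefficient 2,
    degradation 0.1/h), the TTR->TtrR phosphorylation rate (1e-3/s) and the
    CI influx triggered by the Dummy species (200/h) are stand-ins realizing
    the described bistability.  Events: TTR introduced at 25 h, removed at
    60 h, CI reintroduced (via Dummy) at 80 h.
    """
    m = Model()
    TTR, TtrR, Cro, CI, Dummy = m.base_species("TTR", "TtrR", "Cro", "CI",
                                               "Dummy")
    TtrR.dephospho, TtrR.phospho  # dephospho is the default state

    TTR + TtrR.dephospho >> TTR + TtrR.phospho [1e-3 / u.second]
    TtrR.phospho >> TtrR.dephospho [5 * 1e-3 * 1 / u.second]
    TtrR.phospho >> Cro + TtrR.phospho [50 * 0.02 * 1 / u.min]

    # mutual repression toggle: each protein catalyzes production of the
    # other's repressor-controlled supply
    def repressed_production(r):
        return (20 / u.h) / (1 + (r / 20) ** 2)

    CI >> CI + Cro [repressed_production]
    Cro >> Cro + CI [repressed_production]
    Cro >> Zero [0.1 / u.h]
    CI >> Zero [0.1 / u.h]

    Dummy >> Dummy + CI [200 / u.h]

    CI(200)
    TtrR(50)

    sim = Simulation(TTR | TtrR | Cro | CI | Dummy)
    sim.duration = 120 * u.h
    sim.event_time(25 * u.h, {TTR: 100}, label="introduce inflammation byproduct")
    sim.event_time(60 * u.h, {TTR: 0}, label="remove inflammation byproduct")
    sim.event_time(80 * u.h, {Dummy: 1}, label="reintroduce CI")
    return Fixture("detector", m, [sim],
                   {"TTR": TTR, "TtrR": TtrR, "Cro": Cro, "CI": CI,
                    "Dummy": Dummy})


def phage() -> Fixture:
    """Phage-borne antibiotic-resistance transmission between two bacterial
    populations competing for two resources.

    Structure follows the published description (donors secrete phages using
    the fast resource R1; phages infect sensitive receivers, conferring
    resistance; dead receivers absorb phages; antibiotics are introduced in a
    second phase).  All rate constants and initial counts are stand-ins.
    """
    m = Model()
    Donor, Receiver, Phage, R1, R2, Dead, Antibiotic = m.base_species(
        "Donor", "Receiver", "Phage", "R1", "R2", "Dead", "Antibiotic")
    Receiver.sensitive, Receiver.resistant

    # replication consumes resources; R1 is taken up faster than R2
    Donor + R1 >> 2 * Donor [1e-3 / u.h]
    Donor + R2 >> 2 * Donor [2e-4 / u.h]
    Receiver + R1 >> 2 * Receiver [1e-3 / u.h]
    Receiver + R2 >> 2 * Receiver [2e-4 / u.h]

    # phage production consumes R1 only
    Donor + R1 >> Donor + Phage [5e-4 / u.h]

    # infection transmits the resistance gene
    Phage + Receiver.sensitive >> Receiver.resistant [1e-3 / u.h]

    # death bookkeeping: dead receivers still bind (and remove) phages
    Receiver >> Dead [0.01 / u.h]
    Phage + Dead >> Dead [1e-3 / u.h]

    Donor(10)
    Receiver(100)
    R1(5000)
    R2(5000)

    s1 = Simulation(Donor | Receiver | Phage | R1 | R2 | Dead)
    s1.duration = 30 * u.h

    Antibiotic + Receiver.sensitive >> Antibiotic [0.1 / u.h]
    Antibiotic(10)

    s2 = Simulation(Donor | Receiver | Phage | R1 | R2 | Dead | Antibiotic)
    s2.duration = 30 * u.h

    return Fixture("phage", m, [s1, s2],
                   {"Donor": Donor, "Receiver": Receiver, "Phage": Phage,
                    "R1": R1, "R2": R2, "Dead": Dead,
                    "Antibiotic": Antibiotic})


def lysis() -> Fixture:
    """Synchronized bacterial lysis driven by quorum sensing.

    Cells grow logistically and secrete AHL; high AHL switches on production
    of the intracellular lysis enzyme (Hill kinetics), which kills cells,
    collapsing the population and restarting the cycle.  All constants are
    stand-ins realizing the described oscillation (the sharp quorum threshold
    uses Hill coefficient 10, which puts the system in the relaxation-
    oscillation regime).
    """
    m = Model()
    Cell, AHL, Lysis = m.base_species("Cell", "AHL", "Lysis")

    Cell >> 2 * Cell [lambda c: (1.0 / u.h) * (1 - c / 4000) * c]
    Cell >> Cell + AHL [2 / u.h]
    AHL >> Zero [0.5 / u.h]

    def lysis_production(a):
        return (300 / u.h) * (a ** 10) / (4000 ** 10 + a ** 10)

    AHL >> AHL + Lysis [lysis_production]
    Lysis >> Zero [2 / u.h]
    Cell + Lysis >> Lysis [0.05 / u.h]

    Cell(100)

    sim = Simulation(Cell | AHL | Lysis)
    sim.duration = 100 * u.h
    return Fixture("lysis", m, [sim], {"Cell": Cell, "AHL": AHL,
                                       "Lysis": Lysis})


def xor_gate() -> Fixture:
    """Distributed XOR gate: three NOR-gate colonies plus an output buffer.

    Colony locations are the characteristics c1..c4 of Location; the inputs
    Ara and aTc, the wire AHL, the intermediate OC12 and the output YFP are
    mortal, movable species.  NOR gates are modeled as doubly repressed
    production (Hill coefficient 4, threshold 50 counts); the buffer is a
    Hill-activated YFP source.  Input strengths are the sweep parameters
    ara_r and atc_r (counts/h).  All constants are stand-ins realizing the
    described logic.
    """
    m = Model()
    Mortal, Location = m.base_species("Mortal", "Location")
    Location.c1, Location.c2, Location.c3, Location.c4
    PBad, PTet, Pcl, PLas, Movable = m.new(Location, "PBad", "PTet", "Pcl",
                                           "PLas", "Movable")
    Ara, aTc, Cl, YFP, AHL, OC12 = m.new(Mortal * Movable,
                                         "Ara", "aTc", "Cl", "YFP", "AHL",
                                         "OC12")

    ara_r, atc_r = m.parameters(ara_r=[0.0, 200.0], atc_r=[0.0, 200.0])

    Mortal >> Zero [1 / u.h]

    # inputs are supplied at the colonies where they act
    for loc in ("c1", "c2"):
        Zero >> Ara.c(loc) [lambda: ara_r * (1 / u.h)]
    for loc in ("c1", "c3"):
        Zero >> aTc.c(loc) [lambda: atc_r * (1 / u.h)]

    # signal transport between colonies
    Movable.c1 >> Movable.c2 [0.5 / u.h]
    Movable.c1 >> Movable.c3 [0.5 / u.h]
    Movable.c2 >> Movable.c4 [0.5 / u.h]
    Movable.c3 >> Movable.c4 [0.5 / u.h]

    K, n, k_prod = 50, 4, 2000 / u.h

    def nor_rate(r1, r2):
        return k_prod / ((1 + (r1 / K) ** n) * (1 + (r2 / K) ** n))

    # colony 1: AHL = NOR(Ara, aTc)
    Ara.c1 + aTc.c1 >> Ara.c1 + aTc.c1 + AHL.c1 [nor_rate]
    # colony 2: OC12 = NOR(AHL, Ara)
    AHL.c2 + Ara.c2 >> AHL.c2 + Ara.c2 + OC12.c2 [nor_rate]
    # colony 3: OC12 = NOR(AHL, aTc)
    AHL.c3 + aTc.c3 >> AHL.c3 + aTc.c3 + OC12.c3 [nor_rate]
    # buffer: YFP activated by OC12
    OC12.c4 >> OC12.c4 + YFP.c4 [
        lambda o: (400 / u.h) * (o ** 2) / (50 ** 2 + o ** 2)]

    sim = Simulation(PBad | PTet | Pcl | PLas | Ara | aTc | Cl | YFP | AHL
                     | OC12)
    sim.duration = 24 * u.h
    return Fixture("xor", m, [sim],
                   {"Ara": Ara, "aTc": aTc, "YFP": YFP, "AHL": AHL,
                    "OC12": OC12, "Location": Location, "Movable": Movable,
                    "ara_r": ara_r, "atc_r": atc_r})


_BUILDERS = {
    "tree": tree,
    "annihilation": annihilation,
    "antimony_demo": antimony_demo,
    "detector": detector,
    "phage": phage,
    "lysis": lysis,
    "xor": xor_gate,
}


def available_fixtures() -> list[str]:
    return sorted(_BUILDERS)


def build_fixture(name: str) -> Fixture:
    """Build a named fixture; raises ``ModelError`` for unknown names."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ModelError(f"unknown fixture {name!r}; available: "
                         f"{', '.join(available_fixtures())}") from None
    return builder()
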