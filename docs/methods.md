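# Methods

## The meta-species model

A model registry owns base meta-species, each contributing one fresh
*dimension* (axis) to a shared state space.  Characteristics added to a base
species become the ordered values along its axis; the first one added is the
axis default.  Characteristic names are unique per registry — one dimension
per name — which is what keeps dot-queries unambiguous without ever naming a
dimension.  The flip side is that two independent axes cannot reuse a value
name (`Location.green` after `Colored.green` is an error by construction).

Product meta-species (`*`) concatenate their parts' dimensions (deduplicated
by identity, first-appearance order) and take the union of ancestors;
derived meta-species (`Model.new`) share the parent's dimensions but have
their own name, so their concrete species are disjoint from the parent's and
from each other's.  Concrete species are enumerated lexicographically:
dimensions in dimension order, characteristics in insertion order, so the
first state is the all-defaults state and enumeration is deterministic
across runs.  A species name is the meta-species name followed by one
characteristic per non-empty dimension (`Tree.young.green.dense`).

Adding a genuinely new characteristic is only legal on a base meta-species.
Refining a query twice along the same dimension is an error rather than a
silent replacement — replacement would hide typos.  Names are explicit
constructor arguments throughout; the package does not inspect host-language
variable names.

## Meta-reactions and expansion

A meta-reaction pairs reactant terms (query + multiplicity) with product
terms (assignments + multiplicity) and a rate.  Reactions are recorded on
the registry and are visible to every descendant of any reactant
meta-species.  Compilation:

1. Multiplicities are unrolled into unit slots.
2. Each reactant slot collects its *applicable bindings*: every simulated
   meta-species equal to or descending from the slot's meta-species
   contributes its query-matching states, in simulated-declaration order
   then state order.
3. One concrete reaction is emitted per element of the Cartesian product of
   the binding lists — ordered tuples, no symmetric merging and no
   deduplication.  Two slots of the same base meta-species may bind
   different inheritors (cross-pairing is allowed).
4. Products are matched to reactants by cyclic round-robin: for each product
   left-to-right, scan the reactant slots cyclically starting after the
   previous match for that product's meta-species; a match requires an
   identical meta-species.  A matched product starts from the bound reactant
   state; an unmatched product is born in its meta-species' all-default
   state.  Either way the product term's dot-assignments then override the
   assigned dimensions.  An unmatched product whose meta-species is not
   simulated is a compile error (there is no unique born state to choose).
5. The rate is resolved per binding tuple.  Callbacks receive one reactant
   handle per unit slot (a callback may declare fewer positional parameters
   and receives a prefix).  A result that references at least one reactant
   is a full rate expression; otherwise it is a mass-action constant.
   Zero-valued constants drop the expanded reaction.  Null reactions
   (products identical to reactants) are kept.

Every concrete reaction carries provenance: the originating meta-reaction
and the bound state tuple.

## Units

Quantities live on three integer exponent axes — time, volume, substance —
with canonical basis (second, liter, count).  Moles are scaled counts
(Avogadro); molar is mol/liter; a year is 365.25 days.  Addition requires
equal dimension vectors; multiplication adds them.  `to_canonical` is
idempotent and alias round-trips are exact to 1 part in 1e12.

Rate-constant checking against the reaction order `n` accepts:

- `time^-1 · (count/volume)^(1-n)` — concentration-based; the count-based
  firing rate divides by `V^(n-1)` (the Antimony export renders this as the
  explicit `_vol^-(n-1)` factor);
- pure `time^-1` for `n ≥ 2` — interpreted as a count-based propensity
  constant in the declared simulation volume.  This convention is what makes
  count-style models (`A + B >> Zero [0.1/h]` with counts in a 1 ml volume)
  well-formed; it is a package convention, stated here prominently;
- dimensionless constants — treated as concentration-based with the volume
  factor rendered; in fully dimensionless models the time unit is arbitrary
  (canonical seconds if mixed with united quantities).

Species amounts are molecule counts and therefore dimensionless in rate
expressions; an expression used as a full rate must evaluate to counts/time,
concentration/time (multiplied by `V`), or be fully dimensionless.

## Simulation

State variables are counts.  The deterministic solver wraps
`scipy.integrate.solve_ivp` (LSODA, rtol 1e-6 / atol 1e-9 by default,
configurable per phase).  Trigger times — condition events and
condition-based durations — are located by scanning the dense output on a
400-point grid per segment and bisecting the first rising edge to
1e-9 of the phase duration; very brief condition excursions between scan
points can in principle be missed.  Negative excursions are clipped to zero
(warning beyond −1e-12); rate evaluation floors amounts at zero.

The stochastic solver is the classic direct-method SSA with
falling-factorial propensities, reproducible per run with seed
`seed + run_index` (`numpy` PCG64).  Conditions are checked after every
firing, so condition-terminated stop times are exact first-passage times at
the resolution of the jump process.  Non-integer initial amounts (typical at
a deterministic→stochastic phase boundary) are rounded with a warning.

Events fire at most once: time events at their time, condition events on a
rising edge (a condition already true at phase start must first become false
to arm).  Assignments are atomic.  Parameter-valued mass-action constants
and parameter references inside expressions are looked up at simulation
time, so parameter events affect them; constants already folded to numbers
are not affected.

Chained simulations hand the final amounts of phase *i* to phase *i+1* by
species name; species new in a later phase start at their declared initial
amounts.  Condition-based durations run against a cap (`condition_cap`,
default 1e6 canonical time units) so a never-satisfied condition cannot hang
a run.  The default output grid is 250 evenly spaced points per phase.
Deterministic phases are computed once and shared across stochastic runs
with identical initial states.

Declaring a parameter with several values turns `run()` into a full
factorial sweep; cell seeds are offset by cell index; cells are keyed by the
full (name, value) assignment.  Sweeps recompile per cell, which keeps the
semantics of swept constants trivially correct at the cost of recompilation.

Mean/standard-deviation summaries resample runs of different lengths onto
the longest run's grid with previous-value interpolation (shorter runs hold
their final value) — appropriate for jump processes; for smooth
deterministic ensembles the per-run trajectories are exact.

## Exports

The Antimony writer emits the minimal dialect: `model <name>`, species and
`_vol` initializations annotated `dimensionless`, one reaction line per
compiled reaction in compiled order, `end`.  Mass action renders as species
× constant × `_vol^-(n-1)` (the factor omitted for unimolecular reactions);
expressions render as fully parenthesized infix.  Dots in species names are
sanitized to underscores (with a collision check) since Antimony identifiers
cannot contain dots.

The SBML writer produces Level 3 Version 1 documents: one compartment sized
to the simulation volume, species as substance amounts
(`hasOnlySubstanceUnits`), kinetic laws as MathML trees, events with time or
amount-condition triggers.  The XML is generated directly and checked
structurally in the tests (well-formedness, element counts, kinetic-law
presence).

The declarative model file (YAML or JSON) mirrors the builder API
one-to-one; reactions listed inside a simulation entry are declared
immediately before that phase is constructed, which encodes multi-phase
protocols' snapshot semantics.  Rates written as Python callbacks are not
serializable (file-born expression rates round-trip through their rendered
form).

## Fixture models and what they show

The showcase fixtures in `metareact.zoo` fix the network *structure*; where
the underlying descriptions leave rate constants unspecified, the fixtures
use stand-ins, stated in each builder's docstring, chosen once to realize
the described qualitative behavior:

- **tree** — 12 species; aging (6 reactions), death (12), dense-location
  competition (9), replication (6), two-parent reproduction (144: the rate
  callback returns 100/year when the parents share location and color,
  1/year otherwise), and a three-step color cycle (12).
- **annihilation** — published rates and initial concentrations; phase 1
  deterministic growth for 3 h, phase 2 stochastic with the annihilation
  reaction and stop condition `(A <= 0) | (B <= 0)`.
- **antimony_demo** — the canonical export model (7 reactions).
- **detector** — the printed phospho-relay constants plus a stand-in
  Cro/CI toggle (production 20/h, threshold 20, Hill 2, degradation 0.1/h)
  and timed events at 25 h / 60 h / 80 h.
- **phage**, **lysis**, **xor** — structural translations with stand-in
  constants; the lysis oscillator uses a sharp quorum threshold (Hill 10) to
  sit in the relaxation-oscillation regime, and the XOR gate uses Hill-4
  double repression so the NOR stages do not leak.

Passing fixture tests therefore demonstrates the compiler and solvers
reproduce the *described dynamics* of these systems under the stand-in
constants; they do not calibrate against the original experimental data.

## Known limitations

- No binding-site/graph semantics: complexes are modeled as explicit
  species, so polymer-style models grow combinatorially.
- Expansion is eager; there is no network-free simulation.
- One compartment; no spatial structure.
- The direct-method SSA only (no next-reaction method or tau-leaping).
- Condition-event re-arming is one-shot by design.
- SBML export only (no import), and parameters are exported at their
  current values.
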