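"""Export a compiled model as Antimony text (and SBML).

The model derives three mortal, replicating species A, B, C from one pair of
base species, adds a combination reaction A + B -> C, and prints the full
Antimony block: death reactions render as mass action ("A * 1"), the
bimolecular reaction carries the volume factor ("_vol^-1"), and the
saturating replication rate renders as an infix expression.
"""

from metareact import write_sbml
from metareact.zoo import build_fixture

fixture = build_fixture("antimony_demo")
print(fixture.phases[0].generate_antimony("demo")[0])

sbml = write_sbml(fixture.compile(), "demo")
print(f"SBML document: {len(sbml.splitlines())} lines, "
      f"{sbml.count('<species ')} species, {sbml.count('<reaction ')} reactions")
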