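"""Build the two-location tree model and inspect its compiled network.

Four base species (Age, Colored, Mortal, Location) combine into a Tree
meta-species with 2 x 3 x 1 x 2 = 12 concrete species; the reproduction
meta-reaction alone expands into 144 reactions (12 x 12 ordered parent
pairs).  The simulation prints the young/old split after 30 years.
"""

from metareact.zoo import build_fixture

fixture = build_fixture("tree")
Tree = fixture.species["Tree"]

compiled = fixture.compile()
print(f"species: {len(compiled.species)}")
print(f"reactions: {len(compiled.reactions)}")
print("first species:", ", ".join(s.name for s in compiled.species[:3]), "...")

res = fixture.chained.run()
young = res[Tree.young][0][-1]
old = res[Tree.old][0][-1]
print(f"after 30 years: {young:.0f} young trees, {old:.0f} old trees")
print("(query access sums the 6 matching concrete species per age class)")
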