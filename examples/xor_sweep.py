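"""Factorial parameter sweep over the distributed XOR gate.

The two input strengths ara_r and atc_r each take the values {0, 200}
counts/h, so the sweep runs 2 x 2 = 4 cells.  The YFP output after 24 h is
high only when exactly one input is present — the XOR truth table.
"""

from metareact.zoo import build_fixture

fixture = build_fixture("xor")
res = fixture.chained.run(seed=0)

print(f"{'ara_r':>6} {'atc_r':>6} {'YFP(24h)':>10}")
for assignment, cell in res:
    values = dict(assignment)
    yfp = cell.final("YFP.c4")[0]
    print(f"{values['ara_r']:>6.0f} {values['atc_r']:>6.0f} {yfp:>10.1f}")
print("high output only off the diagonal: the circuit computes XOR")
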