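"""Bistable inflammation detector driven by timed events.

A Cro/CI mutual-repression toggle starts in the low-Cro (high-CI) state.
Introducing the inflammation byproduct TTR at 25 h phosphorylates the
response regulator and floods the cell with Cro, flipping the toggle; the
high-Cro state persists after TTR is removed at 60 h (that is the memory),
and only reintroducing CI at 80 h resets it.
"""

import warnings

import numpy as np

from metareact.zoo import build_fixture

warnings.filterwarnings("ignore", message="deterministic solution went negative")

fixture = build_fixture("detector")
res = fixture.chained.run()

tr = res.trajectories[0]
hours = tr.time / 3600.0
cro = res[fixture.species["Cro"]][0]
ci = res[fixture.species["CI"]][0]

for h in (20, 40, 59, 75, 100, 119):
    i = np.searchsorted(hours, h)
    state = "high-Cro" if cro[i] > ci[i] else "low-Cro"
    print(f"t = {h:>3} h: Cro = {cro[i]:>8.1f}  CI = {ci[i]:>7.1f}  -> {state}")
print("the toggle remembers the TTR pulse (high-Cro at 75 h) and resets "
      "after CI is reintroduced")
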