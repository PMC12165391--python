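"""Define a model in the declarative YAML schema and run it from the file.

The same two-phase annihilation protocol as examples/mutual_annihilation.py,
but written as data: the second simulation entry declares the annihilation
reaction locally, which reproduces the snapshot semantics of the builder
API.  The file can also be driven from the shell:

    metareact validate annihilation.yaml
    metareact simulate annihilation.yaml --seed 1 --runs 20
"""

import tempfile
from pathlib import Path

import numpy as np
import yaml

from metareact import read_model_file

DOC = {
    "name": "annihilation",
    "base_species": [{"name": "A"}, {"name": "B"}],
    "reactions": [
        {"reactants": ["A"], "products": ["2*A"], "rate": "1.05/h"},
        {"reactants": ["B"], "products": ["2*B"], "rate": "1/h"},
    ],
    "initial": [
        {"species": "A", "amount": "1/ml"},
        {"species": "B", "amount": "1/ml"},
    ],
    "simulations": [
        {"species": ["A", "B"], "duration": "3 h", "volume": "1 ml"},
        {"species": ["A", "B"],
         "duration": {"condition": "A <= 0 or B <= 0"},
         "method": "stochastic", "volume": "1 ml",
         "runs": 50, "seed": 3, "condition_cap": "500 h",
         "reactions": [
             {"reactants": ["A", "B"], "products": ["Zero"], "rate": "0.1/h"},
         ]},
    ],
}

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "annihilation.yaml"
    path.write_text(yaml.safe_dump(DOC, sort_keys=False))
    model, chained = read_model_file(path)
    print(f"phase 1: {len(chained.phases[0].compile().reactions)} reactions; "
          f"phase 2: {len(chained.phases[1].compile().reactions)} reactions")
    import warnings
    warnings.filterwarnings("ignore", message="non-integer initial amounts")
    res = chained.run()
    a = np.array(res.final("A"))
    print(f"A survives in {np.sum(a > 0)} of {len(res)} runs")
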