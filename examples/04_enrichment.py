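"""Over-representation analysis of a selected list against GMT gene sets.

The table mirrors the usual pathway-report layout: Count (selected
members), PH (pathway total within the tested background), Percent =
100*Count/PH, a hypergeometric p and a Benjamini-Hochberg q.
"""

import numpy as np

from tmtdiff import GeneSetCollection, ora

rng = np.random.default_rng(3)
background = [f"GENE{i}" for i in range(3000)]
selected = background[:150]  # pretend these came out of the differential call

sets = GeneSetCollection()
sets.add("RIBOSOME", background[:42] + background[150:244], "true signal: 42 of 136 selected")
sets.add("SYNAPSE", background[:18] + background[244:311], "true signal: 18 of 85 selected")
for i in range(4):
    sets.add(f"RANDOM{i}", rng.choice(background, 100, replace=False), "no enrichment")

table = ora(selected, background, sets)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\nPercent reads as: RIBOSOME 42/136 -> 30.9% of the pathway is in the "
      "selection; the hypergeometric p asks whether that beats chance given "
      f"{len(selected)} selected out of {len(background)}.")
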