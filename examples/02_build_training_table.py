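"""Monte Carlo dataset assembly: sample the control lattice, simulate,
filter to physiologic ranges, apply bias corrections and normalize.

Uses a small batch so the example runs in under a minute; the full training
protocol is the same with a larger n.
"""

import pandas as pd

from voxphys import default_params
from voxphys.dataset import build_table
from voxphys.synth import run_batch, sample_controls

params = default_params()
controls = sample_controls(n=300, seed=7, params=params)
rows, failures = run_batch(controls, params)
print(f"{len(rows)} phonating simulations, {len(failures)} rejected "
      "(no oscillation / blowup)")

table, tally = build_table(pd.DataFrame(rows), seed=7)
print(f"physiological filter: {tally}")
print(f"train rows: {len(table.train)}, test rows: {len(table.test)}")
print("\nnormalization ranges (physical units):")
print(pd.DataFrame({"min": table.col_min, "max": table.col_max}).round(2))
# Targets: ps [cm H2O] (bias-corrected), pc [cm H2O], a_CT and a_TA in [0,1].
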