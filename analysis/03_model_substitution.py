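"""Apply the dose-escalated walnut-for-meat replacement to every recall day
and summarize the applied deltas, the cap rule and clipping frequency.

Writes results/substitution_summary.csv.
"""

import numpy as np
import pandas as pd

from common import DOSES, RESULTS_DIR
from dietswap.core import read_cohort
from dietswap.substitution import DoseLevel, meat_oz_equivalents, substitute

persons = read_cohort(RESULTS_DIR / "included")

rows = []
for d in DOSES:
    dose = DoseLevel(d)
    removed, clipped, at_cap = [], 0, 0
    deltas = {"energy": [], "fiber": [], "vitamin_b12": [], "cholesterol": []}
    n_days = 0
    for p in persons:
        for day in p.days:
            res = substitute(day, dose)
            n_days += 1
            removed.append(res.meat_removed_oz)
            clipped += res.clipped
            at_cap += res.meat_removed_oz < dose.meat_target_oz - 1e-9
            for k in deltas:
                deltas[k].append(getattr(res.delta, k))
    rows.append({
        "dose_oz": d,
        "mean_meat_removed_oz": np.mean(removed),
        "pct_days_capped_below_dose": 100 * at_cap / n_days,
        "pct_days_clipped": 100 * clipped / n_days,
        **{f"mean_delta_{k}": np.mean(v) for k, v in deltas.items()},
    })

summary = pd.DataFrame(rows)
summary.round(3).to_csv(RESULTS_DIR / "substitution_summary.csv", index=False)
print(summary.round(2).to_string(index=False))
print("\nthe cap rule binds on most days at higher doses: mean removal stays "
      "below the nominal dose once reported meat runs out")
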