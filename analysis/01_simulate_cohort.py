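"""Generate the synthetic two-day recall cohort, survey design, price table
and ground-truth record that every later stage consumes.

Writes results/data/{persons,food_records,weights,prices,cpi}.csv and
truth.json.
"""

import json

import pandas as pd

from common import DATA_DIR, N_PERSONS, SEED, load_design  # noqa: F401
from dietswap.core import write_cohort
from dietswap.simulate import SimulationConfig, generate_cohort, generate_prices

config = SimulationConfig(seed=SEED, n_persons=N_PERSONS)
persons, design, truth = generate_cohort(config)
DATA_DIR.mkdir(parents=True, exist_ok=True)
write_cohort(persons, DATA_DIR)

pd.DataFrame({
    "person_id": design.person_ids,
    "base_weight": design.base_weights,
    **{f"rep_{r}": design.replicate_weights[:, r]
       for r in range(design.n_replicates)},
}).to_csv(DATA_DIR / "weights.csv", index=False)

prices, cpi = generate_prices(config)
prices.table.to_csv(DATA_DIR / "prices.csv", index=False)
cpi.table.to_csv(DATA_DIR / "cpi.csv", index=False)
(DATA_DIR / "truth.json").write_text(json.dumps({
    "pop_mean": truth.pop_mean,
    "frac_below_ear": truth.frac_below_ear,
    "frac_above_ai": truth.frac_above_ai,
}, indent=2))

both = sum(p.n_days == 2 for p in persons)
print(f"simulated {len(persons)} respondents (seed {SEED}); "
      f"{both} ({100 * both / len(persons):.0f}%) completed both recall days")
print(f"wrote cohort files to {DATA_DIR}")
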