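# dietswap

Food-pattern substitution modeling for 24-hour dietary-recall surveys:
what happens to nutrient intake, diet quality and food spending when part
of the meat in a population's diet is replaced by walnuts, dose by dose.

Because 1 oz of cooked meat and 0.5 oz of nuts each count as 1 oz
equivalent of the USDA Protein Foods group, the package models the
replacement of 1, 2, 3 and 4 oz of meat (meat + cured meat + organ meat;
poultry excluded) with 0.5, 1, 1.5 and 2 oz of walnuts, capped at each
person's reported meat. Downstream of the swap it estimates:

- **usual-intake distributions** per nutrient via the NCI-style amount
  model — a Box-Cox linear mixed model g(Y_ij; λ) = x_ij′β + u_i + e_ij
  separating within- from between-person variance, back-transformed by
  Gauss–Hermite quadrature — with EAR cut-point / AI tail fractions;
- **HEI-2015 diet quality** (13 components, 0–100) by the population-ratio
  method on day-1 recalls;
- **survey-weighted inference** with Fay-adjusted balanced-repeated-
  replication variance and the strict non-overlapping-95%-CI significance
  rule;
- **daily food cost** under CPI-adjusted item prices and the same cap rule.

Real dietary-survey microdata cannot be redistributed, so the package
ships a first-class synthetic cohort generator that emulates the survey's
structure (two non-consecutive recall days with 79% day-2 completion,
demographic strata, skewed amounts with known variance components,
replicate weights, price tables) and records the generating truth, letting
every estimator be validated against known answers.

## Worked example

```python
from dietswap.simulate import SimulationConfig, generate_cohort
from dietswap.cohort import apply_exclusions, group_members
from dietswap.hei import population_ratio_score
from dietswap.substitution import DoseLevel, substitute

persons, design, truth = generate_cohort(SimulationConfig(seed=2, n_persons=600))
included, log = apply_exclusions(persons)

day = included[0].day_record(1)
res = substitute(day, DoseLevel(4.0))
print(res.meat_removed_oz, res.delta.energy, res.delta.fiber)

children = [p for p in group_members(included, "Child 4-18") if p.day_record(1)]
_, current = population_ratio_score(children, design)
_, dosed = population_ratio_score(children, design, dose_meat_oz=4.0)
print(round(current.point, 1), round(dosed.point, 1))
```

prints (seed 2):

```
1.3608502018667747 59.19698378120469 1.292807691773436
54.3 61.0
```

The first line is one person's day: they reported only 1.36 oz of meat,
so the 4-oz dose is capped at 1.36 oz removed and 0.68 oz of walnuts
added, raising that day's energy by 59 kcal and fiber by 1.3 g (each
replaced ounce swaps 49 kcal of meat for 92.5 kcal of walnuts and adds
0.95 g of fiber). The second line shows the children's population-ratio
HEI-2015 total rising from 54.3 to 61.0 under the full replacement —
driven, as in the dose-escalation analysis this package implements, by the
fatty-acid ratio, seafood-and-plant-protein and sodium components.

A full report (composition table, HEI-by-dose table with significance
flags, per-nutrient usual-intake distributions, cost summary) comes from
the pipeline:

```bash
dietswap report --out results/run --seed 0 --n-persons 1000
```

or stage by stage via `dietswap simulate / cohort / substitute /
usual-intake / hei / cost`. The numbered scripts under `analysis/` run the
same stages as a narrated sequence, writing their tables under `results/`:

```bash
cd analysis
python 01_simulate_cohort.py
python 02_build_analysis_sample.py
...
python 06_cost_analysis.py
```

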