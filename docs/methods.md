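# Methods

## The modeling problem

`dietswap` models what happens to nutrient intake, diet quality and food
spending in a surveyed population when part of the meat in the diet is
replaced by walnuts at escalating doses. Because 1 oz of cooked meat and
0.5 oz of nuts are both 1 oz equivalent of the USDA Protein Foods group,
the replacement ratio is fixed: 0.5, 1, 1.5 and 2 oz of walnuts stand in
for 1, 2, 3 and 4 oz of meat. "Meat" throughout is the sum of the meat,
cured-meat and organ-meat food-pattern categories; poultry, seafood and
eggs are never replaced.

The pipeline has five stages — sample construction, substitution,
usual-intake estimation, HEI-2015 diet-quality scoring, and a food-cost
model — all exercised on a synthetic survey-like cohort whose generating
parameters are known, so every estimator can be scored against ground
truth.

## Substitution model

For a recall day with reported meat `m` and dose `d`, the engine removes
`r = min(d, m)` oz eq (the cap rule: nobody gives up meat they did not
report; a zero-meat day is untouched) and adds `w = 0.5 r` oz of walnuts.
The nutrient change is the linear combination `w·walnut − r·meat` of two
per-ounce composition vectors:

| per oz | energy | protein | SFA | ALA | LA | chol | Ca | Fe | Mg | K | Cu | Zn | folate | vit E | fiber | B12 |
|---|---|---|---|---|---|---|---|---|---|---|---|---|---|---|---|---|
| walnut | 185 kcal | 4.32 g | 1.74 g | 2.57 g | 10.8 g | — | 27.8 mg | 0.825 mg | 44.8 mg | 125 mg | 0.451 mg | 0.876 mg | 27.8 µg | 0.198 mg | 1.9 g | — |
| meat | 49 kcal | 7.1 g | 0.76 g | 0.01 g | — | 20 mg | 2 mg | 0.5 mg | 6 mg | 93 mg | — | 1.2 mg | — | — | — | 0.6 µg |

Components a food is not a meaningful source of contribute zero. Each
recall day is modified independently, and both days are modified; the
modified diet (including its energy) is what the downstream usual-intake
model sees. Modified amounts are clipped at zero; clipping events are
flagged and are rare at realistic intakes (≈0.2% of days at dose 1, ≈7% at
dose 4 on the default cohort, almost entirely vitamin B12 on low-B12
days). Removal is spread proportionally across the three meat
sub-categories, which is order-free and deterministic.

## Usual-intake estimation

Single 24-h recalls are noisy snapshots of a person's long-run intake. For
daily-consumed nutrients we use the amount-only model

g(Y_ij; λ) = x_ij'β + u_i + e_ij,  u_i ~ N(0, σ_u²),  e_ij ~ N(0, σ_e²),

with g the Box-Cox transform (log at λ = 0). Covariates: recall sequence
(day 1 vs 2), 7 age categories (4–8, 9–13, 14–18, 19–30, 31–50, 51–70,
71+), gender, race (4 levels), energy (kcal, centred at 2000), and a
Mon–Thu weekday indicator. An episodic (two-part) model is out of scope:
the nutrients studied here are consumed essentially daily.

The fit is exact maximum likelihood. For a random-intercept model with
cluster sizes 1–2, the marginal covariance is block diagonal; profiling β
and the residual scale leaves a one-dimensional problem in the variance
ratio θ = σ_u²/σ_e², solved by bounded scalar minimization, with an
explicit boundary check at θ = 0. λ is selected over the grid
{0, 0.05, …, 1} by the profile log-likelihood including the Box-Cox
Jacobian term (λ−1)·Σ log y. The fit is cross-checked in the test suite
against statsmodels MixedLM (ML) and against OLS in the λ = 1, σ_u = 0
case; it matches both to ~1e-4 while running ~2 orders of magnitude
faster, which is what makes the 50-replicate calibration experiments
affordable.

A person's usual intake given a between-person effect u is
T_i(u) = E_e[g⁻¹(x_i'β + u + e)], computed by 9-point Gauss–Hermite
quadrature (values of g⁻¹ outside the transform's range are treated as
zero intake). The population distribution of usual intake is the
survey-weighted distribution of T over persons × 100 Monte-Carlo draws of
u per person ("pseudo-persons"), with prediction covariates fixed at each
person's day-1 values and the sequence effect at its day-1 level.
Percentiles use weighted inverse-CDF interpolation with midpoint plotting
positions. Prevalence of inadequacy is the EAR cut-point (weighted
fraction of pseudo-persons below the threshold); for AI nutrients the
fraction above is reported. Substitution can clip an intake to exactly
zero; before fitting, zero amounts receive a continuity floor of half the
smallest positive amount so the transform is defined.

## Diet quality: HEI-2015, population-ratio method

HEI-2015 scores 13 components (9 adequacy, 4 moderation) on energy-
adjusted densities with piecewise-linear standards, summing to 0–100.
Added-sugar energy uses 16 kcal per tsp equivalent and fat energy
9 kcal/g. A zero-SFA diet receives the full fatty-acid-ratio score when
unsaturated fat is present, zero otherwise. Standards live in a config
dataclass, so a later HEI revision can be swapped in.

The population score is computed by the population-ratio method: weighted
mean constituent amounts across persons first (day-1 recalls only), then
densities and scoring — a ratio of means, which differs from the mean of
per-person scores whenever a component caps (a Jensen gap the test suite
demonstrates). CIs come from BRR replicate weights applied to the whole
amounts-then-score chain.

Under substitution the constituent amounts are adjusted per person with
that person's own capped `r`, using published per-ounce adjustment values
specific to the HEI calculation: walnut (per oz) +2.53 g MUFA, +13.4 g
PUFA, +1.74 g SFA, +185 kcal, +2 oz eq total protein, +2 oz eq seafood &
plant proteins, +0.567 mg sodium; meat (per oz) −0.87 g MUFA, −0.12 g
PUFA, −0.76 g SFA, −49 kcal, −1 oz eq total protein, −1 oz eq seafood &
plant proteins, −127 mg sodium. Two quirks of these published values are
preserved deliberately rather than "corrected": the meat subtraction lists
1 oz eq of seafood & plant proteins even though meat is not part of that
component (a `literal_seafood_plant_subtraction` flag, default on,
controls this), and walnut sodium is three orders of magnitude below meat
sodium. This adjustment profile is intentionally separate from the
substitution engine's composition vectors: the two published lists differ
(the HEI one carries MUFA/PUFA/sodium; the nutrient one carries the
micronutrients) and merging them would fabricate values.

## Survey inference

Estimates are survey-weighted; variances use balanced repeated replication
with a Fay coefficient (default 0.3, configurable, tested at 0 too):
Var = (1/(R(1−F)²)) Σ_r (θ̂_r − θ̂)², CI = θ̂ ± 1.96·SE (normal theory; no
df correction since the df handling of the original analysis is not
specified). Significance between a current and a modeled estimate uses
strictly non-overlapping 95% CIs — a shared endpoint counts as overlap.
For usual-intake quantities the replicates re-run only the weighted
aggregation of usual intakes, not the mixed-model fit; refitting per
replicate would multiply cost roughly R-fold for a second-order effect on
the SE of a mean.

## Cost model

Prices are USD per 100 g in a base year, by food code; codes missing from
the price table borrow their food category's median (flagged as imputed).
Prices are inflated per category by CPI ratio target/base. Daily cost sums
grams/100 × price over day-1 records. Replacement cost applies the same
cap rule as the nutrient model — meat here too excludes poultry, even
though the cost-category taxonomy bundles cured meats with poultry — and
charges the walnut price per ounce of walnut added (0.5 r), not per oz eq:
at 0.38 USD/oz meat and 0.26 USD/oz walnuts, each replaced ounce saves
0.38 − 0.13 = 0.25 USD.

## The synthetic cohort

The generator emulates the structure of a two-day national dietary survey
of no-nut consumers; its defaults are the study conditions, not tuning
knobs:

- demographic strata (6 age bands, gender, 4 race groups, income,
  education) at the survey's weighted proportions; day 2 present with
  probability 0.79;
- amounts drawn from the same Box-Cox random-intercept model the estimator
  assumes, with log-scale between/within SDs of roughly 0.2–0.3 / 0.3–0.5
  per nutrient around realistic median intakes, plus shared age, gender,
  race, sequence, weekday and energy effects (most nutrients λ = 0; fiber
  and magnesium λ = 0.3 to exercise transform selection);
- protein-food composition from per-stratum Dirichlet shares calibrated so
  meat supplies roughly half of protein-food oz equivalents (children
  ≈4.4, men ≈7.0, women ≈5.1 oz eq/day), meat split ~72/26/2 across
  meat/cured/organ;
- respondents who exist only to exercise the exclusion cascade (under-4s,
  pregnant/lactating women, unreliable recalls, extreme-energy days, and
  walnut/other-nut consumers at 4%/8%);
- lognormal pseudo-weights with grouped half-sample BRR replicates (16
  variance strata, Hadamard selection pattern, Fay 0.3) that satisfy the
  variance formula's contract without imitating any real survey's PSU
  design;
- per-food-code prices with the meat and nut per-oz prices stored exactly
  as configured (0.38/0.26 USD), ~5% of codes left unpriced to exercise
  imputation, and a per-category CPI series near 2.2%/yr.

Each logical purpose (demographics, amounts, missingness, weights, foods,
prices, truth) draws from its own stream spawned from the master seed, so
turning a stage on or off never perturbs another stage's draws. The
`TruthRecord` carries each person's realized usual intake (Gauss–Hermite
over the within-person noise at the true parameters), the weighted
population mean, Monte-Carlo percentiles, and the true DRI tail fractions.

What the generator does **not** emulate: real food-code taxonomies and
recipe structure, nutrient-nutrient correlations within person-days,
seasonal effects beyond the weekday shift, differential nonresponse, and
the actual magnitudes of any published survey estimate. Passing tests
therefore demonstrate that the estimators recover the truth of a cohort
that obeys their assumptions and that every directional, arithmetic and
calibration property holds — not that real-survey point estimates are
reproduced, which would require the real microdata.

## Numerical and design choices

- Energy screen (500–5000 kcal, bounds inclusive — only strictly outside
  is excluded) applies to day-1 energy; day 1 is always present.
- Exclusion rules fire in a fixed order; each excluded person carries the
  first matching reason, making the accounting reproducible.
- The replacement cap is applied uniformly in the nutrient, HEI and cost
  stages.
- Ages are banded on completed years (`int(age)`), so band gaps like
  18–19 are well-defined for fractional ages.
- λ grid step 0.05 on [0, 1]; the exact grid is configurable.
- 9-point Gauss–Hermite for back-transformation; 21 points in the truth
  record so the oracle is strictly more accurate than the estimator.
- CSV round-trips use `float_precision="round_trip"` so cohort I/O is
  bit-exact.
- Default problem sizes: 1200 respondents for the analysis drivers, 800
  for the shared test cohort, 1000 × 50 replicates for the parameter-
  recovery experiment, 300 × 200 for the BRR coverage experiment —
  chosen to keep Monte-Carlo error comfortably inside the asserted
  tolerances.

## Known limitations

- One-part model only; genuinely episodic components (e.g. seafood ALA in
  a seafood-only diet) would need the two-part extension.
- BRR SEs for usual-intake quantities ignore fit variability (see above).
- The synthetic price composition is not a rebuilt price database;
  aggregate cost changes land in single-digit percent territory but their
  significance pattern is not expected to match any published analysis.
- HEI component scoring treats adequacy components as linear from zero;
  published rounding conventions (scores reported to 0.1) are not applied
  to internal values.
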