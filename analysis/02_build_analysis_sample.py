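"""Apply the exclusion cascade to reach the no-nut analysis sample and
summarize protein-food composition by age-gender group.

Writes results/included/ (cohort files), results/exclusion_log.csv and
results/table2.csv.
"""

from common import DATA_DIR, RESULTS_DIR, load_design
from dietswap.cohort import apply_exclusions, protein_food_summary
from dietswap.core import read_cohort, write_cohort

persons = read_cohort(DATA_DIR)
design = load_design()

included, exclusion_log = apply_exclusions(persons)
out = RESULTS_DIR / "included"
out.mkdir(parents=True, exist_ok=True)
write_cohort(included, out)
(out / "weights.csv").write_bytes((DATA_DIR / "weights.csv").read_bytes())
exclusion_log.to_csv(RESULTS_DIR / "exclusion_log.csv", index=False)

table2 = protein_food_summary(included, design)
table2.round(2).to_csv(RESULTS_DIR / "table2.csv", index=False)

print(f"{len(persons)} respondents -> {len(included)} included "
      f"({len(exclusion_log)} excluded)")
print(exclusion_log["reason"].value_counts().to_string())
print("\nprotein-food composition (weighted means, % shares):")
print(table2.round(1).to_string(index=False))
meat_shares = table2["meats_share_pct"]
print(f"\nmeat contributes {meat_shares.min():.0f}-{meat_shares.max():.0f}% "
      "of protein-food oz equivalents across groups")
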