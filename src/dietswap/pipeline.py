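"""End-to-end orchestration: simulate -> cohort -> substitute ->
usual-intake / HEI / cost -> report, with deterministic seeding and a
provenance manifest.  Stage outputs are plain CSV files so any stage can be
rerun independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import apply_exclusions, protein_food_summary, group_members
from .cost import group_cost_summary
from .hei import population_ratio_score
from .simulate import SimulationConfig, generate_cohort, generate_prices, default_dri
from .substitution import DOSES, DoseLevel, apply_dose_series
from .survey import nonoverlap_significant
from .usual_intake import (
    CovariateDesign,
    estimate_distribution,
    fit_amount_model,
    floor_amounts,
    persondays_frame,
    threshold_fractions,
)

log = logging.getLogger("dietswap")

HEI_REPORT_GROUPS = (
    "Male 4-18", "Female 4-18", "Child 4-18",
    "Male 19+", "Female 19+", "Adult 19+",
)


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    n_persons: int = 1000
    doses: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    nutrients: tuple[str, ...] = ("fiber", "magnesium", "vitamin_b12", "iron")
    n_pseudo: int = 100
    fay: float = 0.3
    hei_groups: tuple[str, ...] = HEI_REPORT_GROUPS
    sim: SimulationConfig | None = None

    def resolved_sim(self) -> SimulationConfig:
        if self.sim is not None:
            return self.sim
        return SimulationConfig(seed=self.seed, n_persons=self.n_persons, fay=self.fay)


def _manifest(config: RunConfig) -> dict:
    cfg = dataclasses.asdict(config)
    cfg["sim"] = dataclasses.asdict(config.resolved_sim())
    for k, v in list(cfg["sim"]["nutrient_params"].items()):
        cfg["sim"]["nutrient_params"][k] = dataclasses.asdict(
            config.resolved_sim().nutrient_params[k])
    blob = json.dumps(cfg, sort_keys=True, default=str)
    return {
        "config": cfg,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
    }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sim = config.resolved_sim()
    persons, design, truth = generate_cohort(sim)
    log.info("simulate: %d respondents", len(persons))

    included, exclusion_log = apply_exclusions(persons)
    log.info("cohort: %d included, %d excluded", len(included), len(exclusion_log))
    paths["exclusion_log"] = out / "exclusion_log.csv"
    exclusion_log.to_csv(paths["exclusion_log"], index=False)

    table2 = protein_food_summary(included, design)
    paths["table2"] = out / "table2.csv"
    table2.round(3).to_csv(paths["table2"], index=False)

    # --- HEI by group x dose with significance flags ---------------------
    hei_rows = []
    for label in config.hei_groups:
        members = [p for p in group_members(included, label)
                   if p.day_record(1) is not None]
        if not members:
            continue
        _, current = population_ratio_score(members, design)
        hei_rows.append({"group": label, "dose_oz": 0.0,
                         "hei_total": current.point, "ci_lower": current.lower,
                         "ci_upper": current.upper, "significant": ""})
        for d in config.doses:
            _, ci = population_ratio_score(members, design, dose_meat_oz=d)
            hei_rows.append({
                "group": label, "dose_oz": d, "hei_total": ci.point,
                "ci_lower": ci.lower, "ci_upper": ci.upper,
                "significant": "*" if nonoverlap_significant(current, ci) else "",
            })
    table3 = pd.DataFrame(hei_rows)
    paths["table3"] = out / "table3.csv"
    table3.round(2).to_csv(paths["table3"], index=False)
    log.info("hei: %d group x dose rows", len(table3))

    # --- usual intake per nutrient x dose ---------------------------------
    dri = default_dri()
    ui_rows = []
    doses_all = (0.0,) + tuple(config.doses)
    modified = {p.person_id: apply_dose_series(
        p, doses=tuple(DoseLevel(d) for d in config.doses)) for p in included}
    for nutrient in config.nutrients:
        for d in doses_all:
            cohort_d = [modified[p.person_id][d] for p in included]
            df = floor_amounts(persondays_frame(cohort_d, nutrient))
            model = fit_amount_model(df, CovariateDesign())
            dist = estimate_distribution(model, cohort_d, design, nutrient,
                                         n_pseudo=config.n_pseudo,
                                         seed=config.seed)
            row = {
                "nutrient": nutrient, "dose_oz": d, "lambda": model.lam,
                "mean": dist.mean.point, "ci_lower": dist.mean.lower,
                "ci_upper": dist.mean.upper,
                "p5": dist.percentiles[4], "p50": dist.percentiles[49],
                "p95": dist.percentiles[94],
            }
            try:
                fr = threshold_fractions(dist, dri, nutrient, cohort_d)
                for key, ci in fr.items():
                    row[key] = ci.point
                    row[f"{key}_lo"] = ci.lower
                    row[f"{key}_hi"] = ci.upper
            except KeyError:
                pass
            ui_rows.append(row)
            log.info("usual-intake: %s dose %.0f lambda=%.2f mean=%.2f",
                     nutrient, d, model.lam, dist.mean.point)
    paths["usual_intake"] = out / "usual_intake.csv"
    pd.DataFrame(ui_rows).to_csv(paths["usual_intake"], index=False)

    # --- cost --------------------------------------------------------------
    prices, cpi = generate_prices(sim)
    all_codes = sorted({f.food_code for p in included for f in p.foods})
    code_cat = {f.food_code: f.wweia_category for p in included for f in p.foods}
    # map WWEIA labels back onto price categories for imputation
    cat_map = {"Protein Foods-Meats": "meat", "Fruits and Vegetables": "produce",
               "Grains": "grain", "Milk and Dairy": "dairy",
               "Mixed Dishes": "mixed", "Nuts and Seeds": "nuts"}
    prices = prices.impute_missing(
        all_codes, {c: cat_map[code_cat[c]] for c in all_codes})
    from .cost import inflation_adjust
    prices = inflation_adjust(prices, cpi, sim.price_base_year, sim.price_target_year)
    cost_table = group_cost_summary(
        included, design, prices, tuple(DoseLevel(d) for d in config.doses),
        meat_price_per_oz=sim.meat_price_per_oz,
        walnut_price_per_oz=sim.walnut_price_per_oz)
    paths["cost"] = out / "cost.csv"
    cost_table.round(4).to_csv(paths["cost"], index=False)
    log.info("cost: %d rows", len(cost_table))

    manifest = _manifest(config)
    manifest["n_included"] = len(included)
    manifest["n_excluded"] = int(len(exclusion_log))
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return paths
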