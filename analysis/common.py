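"""Shared paths and loaders for the numbered analysis drivers."""

from pathlib import Path

import pandas as pd

from dietswap.survey import SurveyDesign

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "results" / "data"
RESULTS_DIR = ROOT / "results"

SEED = 0
N_PERSONS = 1200
DOSES = (1.0, 2.0, 3.0, 4.0)
NUTRIENTS = ("fiber", "magnesium", "potassium", "iron", "vitamin_b12",
             "zinc", "copper", "ala", "cholesterol")


def load_design(data_dir=DATA_DIR) -> SurveyDesign:
    weights = pd.read_csv(Path(data_dir) / "weights.csv", dtype={"person_id": str})
    rep_cols = [c for c in weights.columns if c.startswith("rep_")]
    return SurveyDesign(
        person_ids=weights["person_id"].to_numpy(),
        base_weights=weights["base_weight"].to_numpy(),
        replicate_weights=weights[rep_cols].to_numpy(),
    )
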