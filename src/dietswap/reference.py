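"""Published reference values from the walnut-for-meat replacement study.

These tables are inputs for validation: the protein-food composition table
(group means in oz equivalents with percent shares) and the HEI total-score
table (population-ratio point estimates with 95% CIs per replacement dose,
and whether the published comparison against the current diet was flagged
significant by the non-overlapping-CI rule).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PROTEIN_FOOD_TABLE", "HEI_SCORE_TABLE", "HEIRow"]

# group -> (total oz eq, {source: (mean oz eq, printed share %)})
PROTEIN_FOOD_TABLE: dict[str, tuple[float, dict[str, tuple[float, float]]]] = {
    "Boys": (4.86, {"meats": (2.47, 50.9), "poultry": (1.43, 29.4),
                    "seafood": (0.22, 4.5), "eggs": (0.38, 7.8),
                    "legumes": (0.32, 6.5), "soy": (0.05, 1.0)}),
    "Girls": (3.81, {"meats": (1.71, 44.9), "poultry": (1.21, 31.7),
                     "seafood": (0.21, 5.5), "eggs": (0.37, 9.8),
                     "legumes": (0.26, 6.9), "soy": (0.05, 1.3)}),
    "Children": (4.36, {"meats": (2.11, 48.4), "poultry": (1.32, 30.3),
                        "seafood": (0.21, 4.9), "eggs": (0.38, 8.6),
                        "legumes": (0.29, 6.7), "soy": (0.05, 1.1)}),
    "Men": (6.97, {"meats": (3.44, 49.4), "poultry": (1.71, 24.5),
                   "seafood": (0.65, 9.4), "eggs": (0.60, 8.6),
                   "legumes": (0.53, 7.6), "soy": (0.04, 0.6)}),
    "Women": (5.05, {"meats": (2.20, 43.6), "poultry": (1.32, 26.2),
                     "seafood": (0.58, 11.5), "eggs": (0.53, 10.5),
                     "legumes": (0.38, 7.4), "soy": (0.04, 0.8)}),
    "Adults": (6.06, {"meats": (2.85, 47.1), "poultry": (1.53, 25.2),
                      "seafood": (0.62, 10.2), "eggs": (0.57, 9.3),
                      "legumes": (0.46, 7.5), "soy": (0.04, 0.6)}),
}


@dataclass(frozen=True)
class HEIRow:
    group: str
    current: tuple[float, float, float]                  # point, lo, hi
    doses: tuple[tuple[float, float, float, bool], ...]  # point, lo, hi, starred


HEI_SCORE_TABLE: tuple[HEIRow, ...] = (
    HEIRow("Male 4-8", (51.4, 48.9, 53.8), (
        (57.4, 54.9, 59.8, True), (60.1, 57.7, 62.6, True),
        (62.7, 60.2, 65.2, True), (64.7, 62.4, 67.0, True))),
    HEIRow("Male 9-13", (46.8, 44.3, 49.3), (
        (52.4, 49.8, 54.8, True), (55.3, 52.8, 57.7, True),
        (57.7, 55.3, 60.0, True), (59.8, 57.4, 62.1, True))),
    HEIRow("Male 14-18", (44.6, 42.4, 46.8), (
        (49.8, 47.6, 51.9, True), (52.6, 50.5, 54.8, True),
        (54.9, 52.7, 57.1, True), (57.1, 54.9, 59.2, True))),
    HEIRow("Male 4-18", (47.3, 45.7, 48.9), (
        (52.8, 51.1, 54.5, True), (55.6, 54.0, 57.2, True),
        (58.0, 56.3, 59.7, True), (60.2, 58.6, 61.7, True))),
    HEIRow("Female 4-8", (54.1, 52.2, 56.0), (
        (60.8, 58.8, 62.7, True), (63.8, 61.8, 65.8, True),
        (66.8, 64.7, 68.7, True), (67.6, 65.8, 69.5, True))),
    HEIRow("Female 9-13", (51.6, 49.1, 54.2), (
        (57.3, 54.9, 59.7, True), (59.9, 57.6, 62.3, True),
        (62.5, 60.1, 64.8, True), (63.4, 61.4, 65.4, True))),
    HEIRow("Female 14-18", (48.7, 45.9, 51.5), (
        (54.4, 51.8, 57.1, True), (57.3, 54.7, 60.1, True),
        (59.6, 57.1, 62.1, True), (60.2, 57.9, 62.7, True))),
    HEIRow("Female 4-18", (51.5, 50.1, 53.1), (
        (57.4, 56.1, 58.8, True), (60.2, 58.9, 61.6, True),
        (62.9, 61.6, 64.2, True), (63.6, 62.4, 64.8, True))),
    HEIRow("Child 4-18", (49.1, 47.9, 50.4), (
        (55.0, 53.8, 56.2, True), (57.6, 56.5, 58.8, True),
        (60.2, 59.0, 61.3, True), (61.8, 60.8, 62.8, True))),
    HEIRow("Male 19-50", (49.7, 47.9, 51.7), (
        (53.7, 52.1, 55.3, True), (55.9, 54.3, 57.5, True),
        (58.1, 56.5, 59.7, True), (59.9, 58.4, 61.3, True))),
    HEIRow("Female 19-50", (50.7, 48.4, 53.0), (
        (55.3, 53.1, 57.5, True), (58.1, 56.0, 60.3, True),
        (60.7, 58.7, 62.6, True), (61.4, 59.5, 63.2, True))),
    HEIRow("Adult 19-50", (50.1, 48.4, 51.9), (
        (54.3, 52.8, 55.8, True), (56.8, 55.3, 58.3, True),
        (59.2, 57.7, 60.7, True), (60.5, 59.2, 61.8, True))),
    HEIRow("Male 51-70", (54.0, 51.1, 57.0), (
        (57.3, 54.6, 60.0, False), (59.5, 56.8, 62.3, False),
        (61.8, 59.0, 64.6, True), (63.2, 60.8, 65.6, True))),
    HEIRow("Female 51-70", (56.4, 54.7, 58.1), (
        (60.7, 58.9, 62.5, True), (63.7, 61.9, 65.5, True),
        (65.6, 63.9, 67.2, True), (66.2, 64.5, 67.8, True))),
    HEIRow("Adult 51-70", (55.0, 53.0, 56.9), (
        (58.7, 56.7, 60.7, False), (61.3, 59.3, 63.3, True),
        (63.7, 61.8, 65.6, True), (64.4, 62.7, 66.2, True))),
    HEIRow("Adult 71+", (59.6, 56.4, 62.7), (
        (63.6, 60.8, 66.3, False), (66.5, 63.7, 69.2, True),
        (68.7, 66.0, 71.2, True), (69.2, 66.6, 71.7, True))),
    HEIRow("Male 19+", (51.7, 50.1, 53.2), (
        (55.4, 54.0, 56.8, True), (57.6, 56.2, 59.0, True),
        (59.9, 58.5, 61.3, True), (61.5, 60.2, 62.8, True))),
    HEIRow("Female 19+", (53.5, 51.9, 55.2), (
        (58.0, 56.3, 59.7, True), (60.9, 59.2, 62.6, True),
        (63.2, 61.8, 64.7, True), (63.8, 62.4, 65.3, True))),
    HEIRow("Adult 19+", (52.4, 51.0, 53.8), (
        (56.4, 55.1, 57.8, True), (59.0, 57.6, 60.3, True),
        (61.5, 60.1, 62.8, True), (62.4, 61.2, 63.6, True))),
)
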