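"""Published reference statistics for the adult Thai proximal tibia.

These printed summary tables are the inputs the synthetic population is built
from: per-gender means and standard deviations of the eight directly measured
parameters, the ten strongest pooled Pearson correlations, and the recommended
seven-size tibial-component table (AP, ML in mm, per gender).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "GENDER_SUMMARY",
    "POOLED_SUMMARY",
    "POOLED_CORRELATIONS",
    "DEFAULT_POOLED_R",
    "COMPONENT_SIZES",
    "component_size_table",
]

#: per-gender mean and SD (mm) of the eight generator parameters
GENDER_SUMMARY: dict[str, dict[str, tuple[float, float]]] = {
    "male": {
        "ml": (77.52, 3.22),
        "ap": (49.26, 2.49),
        "map": (51.79, 2.64),
        "lap": (46.73, 2.73),
        "cm": (15.71, 2.65),
        "cl": (16.35, 3.11),
        "mar": (26.00, 1.41),
        "lar": (23.00, 1.38),
    },
    "female": {
        "ml": (67.51, 3.17),
        "ap": (43.45, 2.53),
        "map": (46.65, 2.44),
        "lap": (40.45, 2.37),
        "cm": (12.87, 1.92),
        "cl": (14.20, 2.43),
        "mar": (22.86, 1.43),
        "lar": (20.03, 1.29),
    },
}

#: pooled (both genders, n = 480) mean and SD, incl. the derived aspect ratio
POOLED_SUMMARY: dict[str, tuple[float, float]] = {
    "ml": (72.52, 5.94),
    "ap": (46.36, 3.84),
    "map": (49.22, 3.62),
    "lap": (43.59, 4.05),
    "cm": (14.29, 2.72),
    "cl": (15.28, 2.99),
    "mar": (24.43, 2.11),
    "lar": (21.52, 2.00),
    "ar": (1.57, 0.08),
}

#: the ten strongest pooled pairwise Pearson correlations
POOLED_CORRELATIONS: dict[frozenset[str], float] = {
    frozenset({"ml", "lap"}): 0.859,
    frozenset({"lap", "ap"}): 0.838,
    frozenset({"ml", "map"}): 0.818,
    frozenset({"map", "lap"}): 0.814,
    frozenset({"mar", "lar"}): 0.812,
    frozenset({"ml", "ap"}): 0.811,
    frozenset({"map", "ap"}): 0.802,
    frozenset({"ml", "lar"}): 0.802,
    frozenset({"mar", "ml"}): 0.753,
    frozenset({"mar", "map"}): 0.744,
}

#: pooled r assumed for the unlisted pairs (reported range 0.17–0.74)
DEFAULT_POOLED_R = 0.45

#: recommended tibial component sizes: (size, gender, ap_mm, ml_mm)
COMPONENT_SIZES: list[tuple[int, str, float, float]] = [
    (1, "male", 42.0, 72.0),
    (2, "male", 44.0, 75.0),
    (3, "male", 46.0, 72.0),
    (4, "male", 46.0, 78.0),
    (5, "male", 48.0, 75.0),
    (6, "male", 50.0, 78.0),
    (7, "male", 52.0, 80.0),
    (1, "female", 38.0, 62.0),
    (2, "female", 40.0, 65.0),
    (3, "female", 42.0, 62.0),
    (4, "female", 43.0, 68.0),
    (5, "female", 44.0, 68.0),
    (6, "female", 46.0, 71.0),
    (7, "female", 48.0, 65.0),
]


def component_size_table() -> pd.DataFrame:
    """The recommended component sizes as a tidy SizeTable DataFrame."""
    return pd.DataFrame(
        COMPONENT_SIZES, columns=["size", "gender", "ap_mm", "ml_mm"]
    )
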