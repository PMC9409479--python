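"""Published summary data for the apricot seed wasp (Eurytoma maslovskii).

Group means and validation dates from the post-diapause rearing study that
this package models.  Raw per-individual durations were never released, so
these printed summaries are the fixtures every mean-level computation runs
against: stage mean durations by rearing temperature (cracked-seed experiment,
through adult emergence; intact-seed experiment, through adult exit), the
fitted Weibull phenology parameters, and the observed/predicted Julian dates
used for field validation.

All durations are days, temperatures degC, dates Julian day-of-year.
"""

from __future__ import annotations

import pandas as pd

# Rearing temperatures at which development completed (the 34.3 degC group
# never pupated and contributes no durations).
VIABLE_TEMPERATURES = (14.5, 18.8, 21.3, 24.0, 27.0, 30.2)
FAILURE_TEMPERATURE = 34.3

# Cracked-seed experiment: larvae extracted from the endocarp, followed to
# adult emergence.  Mean durations (days) per group.
EMERGENCE_MEANS = pd.DataFrame({
    "temperature_c": VIABLE_TEMPERATURES,
    "n": [49, 47, 47, 47, 47, 46],
    "larva_days": [10.0, 6.8, 5.0, 4.0, 3.3, 3.1],
    "pupa_days": [29.1, 17.0, 13.7, 11.9, 8.9, 8.5],
    "total_days": [39.1, 23.8, 18.6, 15.8, 12.2, 11.7],
    "male_days": [36.8, 23.3, 18.0, 15.1, 11.3, 11.3],
    "female_days": [40.0, 24.4, 19.3, 16.3, 12.6, 12.1],
    "prolonged_pct": [4.1, 4.3, 2.1, 2.1, 4.3, 21.7],
    "pupation_pct": [95.9, 89.4, 91.5, 93.6, 85.1, 60.9],
    "emergence_pct": [91.8, 85.1, 89.4, 93.6, 83.0, 58.7],
})

# Intact-seed experiment: whole seeds, followed to adult exit from the seed.
EXIT_MEANS = pd.DataFrame({
    "temperature_c": VIABLE_TEMPERATURES,
    "n": [81, 47, 68, 83, 74, 63],
    "total_days": [46.3, 29.7, 23.9, 20.5, 17.0, 16.7],
    "male_days": [44.7, 27.9, 22.4, 19.0, 16.0, 15.8],
    "female_days": [47.3, 31.0, 25.8, 21.4, 17.9, 17.8],
    "prolonged_pct": [1.2, 6.4, 1.5, 1.2, 2.7, 1.6],
    "exit_pct": [90.1, 80.9, 94.1, 94.0, 93.2, 69.8],
    "post_emergence_days": [7.2, 5.8, 5.3, 4.6, 4.7, 5.0],
})

# Fitted two-parameter Weibull phenology (scale a in degree days, shape b).
WEIBULL_PARAMS = {
    "pupation": (63.2202, 6.0138),
    "adult_emergence": (248.2907, 15.8672),
    "adult_exit": (344.9728, 13.5357),
    "male": (313.8498, 21.1625),
    "female": (363.6323, 21.8888),
}

# Headline linear-model thermal traits (LT degC, DD degree days) per stage.
LINEAR_TRAITS = {
    "larva": (8.1, 66.2),
    "pupa": (8.2, 180.8),
    "larva_to_emergence": (8.2, 246.9),
    "larva_to_exit": (7.3, 336.7),
}

# Field-validation rows: observed and model-predicted Julian dates at the
# 10/30/50/70/90% cumulative-flight points for each site-year.
VALIDATION_ROWS = [
    {"year": 2015, "location": "Sunchang",
     "observed": (116, 117, 120, 121, 122), "predicted": (111, 114, 116, 117, 119)},
    {"year": 2015, "location": "Yeongkwang",
     "observed": (116, 117, 119, 120, 121), "predicted": (119, 121, 123, 124, 127)},
    {"year": 2015, "location": "Suncheon",
     "observed": (112, 114, 115, 117, 124), "predicted": (114, 117, 119, 120, 122)},
    {"year": 2015, "location": "Goheung",
     "observed": (112, 114, 115, 120, 124), "predicted": (112, 115, 117, 119, 120)},
    {"year": 2015, "location": "Gwangyang",
     "observed": (112, 115, 117, 121, 124), "predicted": (110, 113, 115, 116, 117)},
    {"year": 2016, "location": "Sunchang",
     "observed": (112, 116, 120, 121, 122), "predicted": (113, 116, 117, 119, 121)},
    {"year": 2016, "location": "Yeongkwang",
     "observed": (110, 114, 119, 121, 124), "predicted": (117, 121, 123, 124, 126)},
    {"year": 2016, "location": "Suncheon",
     "observed": (109, 114, 116, 120, 122), "predicted": (109, 113, 114, 116, 117)},
    {"year": 2016, "location": "Goheung",
     "observed": (105, 109, 114, 116, 121), "predicted": (112, 115, 117, 120, 122)},
    {"year": 2016, "location": "Gwangyang",
     "observed": (106, 110, 111, 112, 115), "predicted": (105, 108, 110, 112, 113)},
    {"year": 2022, "location": "Room",
     "observed": (93, 95, 96, 96, 97), "predicted": (94, 96, 97, 97, 98)},
    {"year": 2022, "location": "Semi-field",
     "observed": (120, 122, 125, 126, 128), "predicted": (117, 122, 124, 125, 127)},
    {"year": 2022, "location": "Suncheon",
     "observed": (108, 111, 113, 114, 117), "predicted": (108, 112, 113, 114, 116)},
]

CUMULATIVE_FLIGHT_POINTS = (0.10, 0.30, 0.50, 0.70, 0.90)


def emergence_rates(stage: str = "total_days") -> pd.DataFrame:
    """(temperature, rate) pairs from cracked-seed mean durations."""
    df = EMERGENCE_MEANS[["temperature_c", stage]].copy()
    df["rate_per_day"] = 1.0 / df.pop(stage)
    return df


def exit_rates(stage: str = "total_days") -> pd.DataFrame:
    """(temperature, rate) pairs from intact-seed mean durations."""
    df = EXIT_MEANS[["temperature_c", stage]].copy()
    df["rate_per_day"] = 1.0 / df.pop(stage)
    return df
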