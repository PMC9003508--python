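"""Reported values from the triplicate inter-laboratory SOC ring trial
that the synthetic cohort emulates.

These numbers parameterise the generator defaults and support internal
consistency checks — in particular, the identity that the pairwise bias
between two laboratory series equals the difference of their means, so
the pairwise bias table is recomputable from the per-series summary
statistics alone.
"""
from __future__ import annotations

import pandas as pd

#: Per-series summary statistics of the reported triplicate dry-combustion
#: SOC measurements (g/kg, n = 75) and their per-sample average.
LAB_SUMMARY = pd.DataFrame(
    {
        "min": [6.16, 6.00, 6.37, 6.18],
        "Q1": [11.16, 10.88, 11.37, 11.12],
        "median": [14.50, 14.38, 14.88, 14.59],
        "Q3": [23.03, 22.79, 24.27, 23.36],
        "max": [35.06, 35.28, 36.26, 35.54],
        "mean": [17.01, 16.91, 17.60, 17.17],
        "SD": [7.73, 7.84, 8.06, 7.87],
        "skewness": [0.52, 0.54, 0.52, 0.53],
    },
    index=["lab_1", "lab_2", "lab_3", "lab_avg"],
)

#: Reported pairwise bias (row minus column, g/kg) between the series.
LAB_PAIRWISE_BIAS = {
    ("lab_1", "lab_2"): 0.10,
    ("lab_1", "lab_3"): -0.59,
    ("lab_2", "lab_3"): -0.69,
}

#: Reported stratum-mean SOC contents (g/kg).
STRATUM_MEANS = {"Devonian": 26.2, "Rotliegend": 10.2, "Jurassic": 14.7}

#: Reported replicate-SD anchors of the laboratory error profile (g/kg).
LAB_SD_ANCHORS = {10.0: 0.21, 25.0: 0.65}


def bias_from_means(a: str, b: str) -> float:
    """Pairwise bias recomputed from the per-series means: mean(a) - mean(b)."""
    return float(LAB_SUMMARY.loc[a, "mean"] - LAB_SUMMARY.loc[b, "mean"])
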