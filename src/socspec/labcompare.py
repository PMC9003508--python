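"""Inter-laboratory agreement analysis for replicate SOC reference series.

A reference table holds one SOC column (g/kg) per laboratory series plus
their per-sample average.  Agreement between series is summarised by
pairwise RMSE, bias (mean row-minus-column difference) and R^2 (squared
Pearson correlation), a paired t-test on the systematic offset, and the
SOC-dependent profile of the per-sample replicate SD.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def lab_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("lab_") and c != "lab_avg"]


def validate_reference_table(table: pd.DataFrame) -> None:
    cols = lab_columns(table)
    if len(cols) < 2:
        raise ValueError("reference table needs at least two laboratory series")
    if (table[cols] <= 0).any().any():
        raise ValueError("SOC values must be positive")
    if "lab_avg" in table.columns:
        if not np.allclose(table["lab_avg"], table[cols].mean(axis=1), atol=1e-9):
            raise ValueError("lab_avg is not the row mean of the laboratory series")


def summary_stats(series: pd.Series | np.ndarray) -> pd.Series:
    """Min, Q1, median, Q3, max, mean, SD and skewness of one SOC series.

    SD uses the n-1 denominator; skewness is the adjusted (bias-corrected)
    Fisher-Pearson sample skewness, reported as 0 for a constant series.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values (skewness undefined)")
    sd = float(np.std(x, ddof=1))
    skew = 0.0 if sd == 0 else float(stats.skew(x, bias=False))
    return pd.Series(
        {
            "min": float(x.min()),
            "Q1": float(np.percentile(x, 25)),
            "median": float(np.median(x)),
            "Q3": float(np.percentile(x, 75)),
            "max": float(x.max()),
            "mean": float(x.mean()),
            "SD": sd,
            "skewness": skew,
        }
    )


@dataclass
class AgreementMatrix:
    """Pairwise RMSE / bias / R^2 between reference series (incl. the average).

    ``bias.loc[a, b]`` is mean(a) - mean(b): antisymmetric.  RMSE and R^2
    are symmetric; the RMSE diagonal is zero.
    """

    rmse: pd.DataFrame
    bias: pd.DataFrame
    r2: pd.DataFrame


def pairwise_agreement(table: pd.DataFrame, include_average: bool = True) -> AgreementMatrix:
    """RMSE, bias and R^2 between every ordered pair of series.

    RMSE = sqrt(mean((a-b)^2)), bias = mean(a-b), R^2 = squared Pearson
    correlation.  The average column, when present, is compared like any
    other series (and is the plain mean over all series).
    """
    validate_reference_table(table)
    cols = lab_columns(table)
    if include_average and "lab_avg" in table.columns:
        cols = cols + ["lab_avg"]
    n = len(cols)
    rmse = pd.DataFrame(np.zeros((n, n)), index=cols, columns=cols)
    bias = pd.DataFrame(np.zeros((n, n)), index=cols, columns=cols)
    r2 = pd.DataFrame(np.ones((n, n)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if i == j:
                continue
            d = table[a].to_numpy() - table[b].to_numpy()
            rmse.loc[a, b] = float(np.sqrt(np.mean(d**2)))
            bias.loc[a, b] = float(np.mean(d))
            if np.std(table[a]) == 0 or np.std(table[b]) == 0:
                raise ValueError("R^2 undefined for a constant series")
            r = float(np.corrcoef(table[a], table[b])[0, 1])
            r2.loc[a, b] = r**2
    return AgreementMatrix(rmse=rmse, bias=bias, r2=r2)


def paired_t_test(a: pd.Series | np.ndarray, b: pd.Series | np.ndarray) -> tuple[float, float]:
    """Classical paired t-test on a-b with n-1 degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equally long series with n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance differences: t statistic undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def sd_by_soc_class(
    table: pd.DataFrame, breakpoints: tuple[float, ...] = (10.0, 25.0)
) -> tuple[pd.Series, float]:
    """Mean per-sample replicate SD within SOC classes, plus the maximum
    absolute deviation between any two series on any sample.

    Samples are binned by their across-series average SOC at the given
    breakpoints; the per-sample SD over series uses the n-1 denominator.
    Empty classes are reported as NaN.
    """
    cols = lab_columns(table)
    if len(cols) < 2:
        raise ValueError("need at least two laboratory series")
    avg = table["lab_avg"] if "lab_avg" in table.columns else table[cols].mean(axis=1)
    per_sample_sd = table[cols].std(axis=1, ddof=1)
    edges = [-np.inf, *breakpoints, np.inf]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(lo):
            labels.append(f"<{hi:g}")
        elif np.isinf(hi):
            labels.append(f">{lo:g}")
        else:
            labels.append(f"{lo:g}-{hi:g}")
    cls = pd.cut(avg, bins=edges, labels=labels)
    class_means = per_sample_sd.groupby(cls, observed=False).mean()
    max_dev = float((table[cols].max(axis=1) - table[cols].min(axis=1)).max())
    return class_means, max_dev
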