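"""Spectral repeatability between replicate measurement series.

Agreement of two replicate spectra is scored with the repeatability
function S_r = 1 / (1 - r), where r is the Pearson correlation between
the two spectra.  Because replicate spectra are nearly identical, r is
close to 1 and insensitive; S_r stretches that top end so that small
repeatability differences become visible.  Larger S_r means more
similar spectra.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import SpectrumSet

logger = logging.getLogger(__name__)

_R_ONE_TOL = 1e-15


def spectral_repeatability(a: np.ndarray, b: np.ndarray) -> float:
    """S_r = 1/(1 - r) for one pair of spectra on the same grid.

    Returns +inf when r is 1 to machine precision (identical spectra);
    such values are flagged and excluded from distribution summaries.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("spectra must be 1-D and equally long")
    if a.size < 3:
        raise ValueError("need at least 3 grid points")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant spectrum")
    r = float(np.corrcoef(a, b)[0, 1])
    if r >= 1.0 - _R_ONE_TOL:
        return float("inf")
    return 1.0 / (1.0 - r)


@dataclass
class RepeatabilitySummary:
    """Distribution summary of per-sample S_r values for one series pair."""

    pair_label: str
    per_sample: pd.Series  # S_r indexed by sample_id (may contain inf)
    q1: float
    mean: float
    q3: float
    sd: float
    cv_percent: float
    n_excluded: int

    def to_row(self) -> dict:
        return {
            "pair": self.pair_label,
            "Q1": self.q1,
            "mean": self.mean,
            "Q3": self.q3,
            "SD": self.sd,
            "CV%": self.cv_percent,
            "n_excluded": self.n_excluded,
        }


def series_repeatability(
    set_a: SpectrumSet, set_b: SpectrumSet, pair_label: str | None = None
) -> RepeatabilitySummary:
    """Per-sample S_r between two series plus its distribution summary.

    Samples are matched by id; quartiles use the linear-interpolation
    ("type 7") convention, SD uses the n-1 denominator and
    CV% = 100 * SD / mean.  Infinite S_r values (identical spectra) are
    excluded from the summary and counted.
    """
    if set_a.grid != set_b.grid:
        raise ValueError("grids differ between series")
    common = [sid for sid in set_a.sample_ids if sid in set(set_b.sample_ids)]
    if not common:
        raise ValueError("no matched sample ids between series")
    pos_a = {sid: i for i, sid in enumerate(set_a.sample_ids)}
    pos_b = {sid: i for i, sid in enumerate(set_b.sample_ids)}
    values = pd.Series(
        [
            spectral_repeatability(set_a.values[pos_a[sid]], set_b.values[pos_b[sid]])
            for sid in common
        ],
        index=pd.Index(common, name="sample_id"),
        name="S_r",
    )
    finite = values[np.isfinite(values)]
    n_excluded = int(len(values) - len(finite))
    if n_excluded:
        logger.warning("excluded %d infinite S_r values from summary", n_excluded)
    if len(finite) == 0:
        q1 = mean = q3 = sd = cv = float("nan")
    else:
        q1 = float(np.percentile(finite, 25))
        q3 = float(np.percentile(finite, 75))
        mean = float(finite.mean())
        sd = float(finite.std(ddof=1)) if len(finite) > 1 else 0.0
        cv = 100.0 * sd / mean if mean > 0 else float("nan")
    label = pair_label or f"{set_a.series_label},{set_b.series_label}"
    return RepeatabilitySummary(
        pair_label=label,
        per_sample=values,
        q1=q1,
        mean=mean,
        q3=q3,
        sd=sd,
        cv_percent=cv,
        n_excluded=n_excluded,
    )
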