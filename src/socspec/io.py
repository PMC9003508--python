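"""CSV round-tripping for spectra and reference tables.

Spectra files carry one row per sample: first column ``sample_id``, one
column per grid point with the grid value as header.  Reference tables
carry ``sample_id, stratum, lab_1..lab_K, lab_avg``.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .labcompare import validate_reference_table
from .spectra import SpectralGrid, SpectrumSet


def write_spectra_csv(spectra: SpectrumSet, path) -> None:
    df = pd.DataFrame(
        spectra.values, columns=[f"{v:g}" for v in spectra.grid.values]
    )
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, index=False)


def read_spectra_csv(path, axis_kind: str, unit: str, series_label: str = "") -> SpectrumSet:
    df = pd.read_csv(path)
    grid = SpectralGrid(axis_kind, np.array([float(c) for c in df.columns[1:]]))
    return SpectrumSet(
        grid=grid,
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        unit=unit,
        sample_ids=df["sample_id"].to_numpy(),
        series_label=series_label,
    )


def write_reference_csv(table: pd.DataFrame, path) -> None:
    validate_reference_table(table)
    table.to_csv(path, index=False)


def read_reference_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_reference_table(table)
    return table
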