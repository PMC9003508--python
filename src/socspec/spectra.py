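"""Spectral containers and preprocessing for diffuse-reflectance soil spectra.

Spectra live on a common strictly increasing grid (wavelength in nm for
VNIR, wavenumber in cm^-1 for MIR; MIR grids are stored ascending even
though plots conventionally reverse the axis).  Reflectance R in (0, 1]
is converted to absorbance A = -log10(R) before any modelling; low
signal-to-noise edge regions are trimmed and spectra resampled to a
uniform increment by linear interpolation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

WAVELENGTH_NM = "wavelength-nm"
WAVENUMBER_CM = "wavenumber-cm-1"
REFLECTANCE = "reflectance"
ABSORBANCE = "absorbance"

#: Retained ranges and increments that reproduce the standard working grids
#: (2100 points for VNIR, 1600 for MIR) after trimming the noisy edges.
DEFAULT_KEEP = {
    "vnir": (401.0, 2500.0, 1.0),
    "mir": (802.0, 4000.0, 2.0),
}


@dataclass(frozen=True)
class SpectralGrid:
    """A strictly increasing spectral axis.

    Parameters
    ----------
    axis_kind:
        ``"wavelength-nm"`` (VNIR) or ``"wavenumber-cm-1"`` (MIR).
    values:
        Strictly increasing axis values, at least two points.
    """

    axis_kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.axis_kind not in (WAVELENGTH_NM, WAVENUMBER_CM):
            raise ValueError(f"unknown axis kind {self.axis_kind!r}")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("grid needs at least two points")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("grid values must be strictly increasing")
        object.__setattr__(self, "values", vals)

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return self.axis_kind == other.axis_kind and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.axis_kind, self.values.tobytes()))


@dataclass
class SpectrumSet:
    """Spectra of one measurement series on a common grid.

    ``values`` is a (samples x grid points) matrix in either reflectance
    (validated to lie in (0, 1]) or absorbance units.
    """

    grid: SpectralGrid
    values: np.ndarray
    unit: str
    sample_ids: np.ndarray
    series_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x grid matrix")
        if self.values.shape[1] != self.grid.n_points:
            raise ValueError(
                f"{self.values.shape[1]} columns vs {self.grid.n_points} grid points"
            )
        if self.values.shape[0] != self.sample_ids.size:
            raise ValueError("one sample_id per row required")
        if self.unit not in (REFLECTANCE, ABSORBANCE):
            raise ValueError(f"unknown unit {self.unit!r}")
        if np.isnan(self.values).any():
            raise ValueError("missing values in spectra")
        if self.unit == REFLECTANCE:
            if (self.values <= 0).any() or (self.values > 1).any():
                raise ValueError("reflectance must lie in (0, 1]")

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(
            grid=self.grid,
            values=self.values.copy(),
            unit=self.unit,
            sample_ids=self.sample_ids.copy(),
            series_label=self.series_label,
        )


def reflectance_to_absorbance(spectra: SpectrumSet, *, floor: float = 1e-6) -> SpectrumSet:
    """Convert reflectance to absorbance, A = -log10(R).

    Non-positive reflectance values (possible only on corrupted input)
    are clipped to ``floor`` first; the clip count is logged.
    """
    if spectra.unit != REFLECTANCE:
        raise ValueError("input unit must be reflectance")
    vals = spectra.values
    n_clip = int((vals <= 0).sum())
    if n_clip:
        logger.warning("clipped %d non-positive reflectance values to %g", n_clip, floor)
        vals = np.clip(vals, floor, None)
    return SpectrumSet(
        grid=spectra.grid,
        values=-np.log10(vals),
        unit=ABSORBANCE,
        sample_ids=spectra.sample_ids.copy(),
        series_label=spectra.series_label,
    )


def absorbance_to_reflectance(spectra: SpectrumSet) -> SpectrumSet:
    """Inverse transform R = 10**(-A) (used for round-trip checks)."""
    if spectra.unit != ABSORBANCE:
        raise ValueError("input unit must be absorbance")
    return SpectrumSet(
        grid=spectra.grid,
        values=10.0 ** (-spectra.values),
        unit=REFLECTANCE,
        sample_ids=spectra.sample_ids.copy(),
        series_label=spectra.series_label,
    )


def trim_and_resample(
    spectra: SpectrumSet,
    keep_min: float,
    keep_max: float,
    increment: float,
) -> SpectrumSet:
    """Trim to [keep_min, keep_max] and resample to a uniform increment.

    The output grid is keep_min, keep_min + increment, ... up to the last
    point <= keep_max (both endpoints inclusive when they align), with
    values linearly interpolated from the native grid.  Requests outside
    the native support raise instead of extrapolating.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    if keep_max <= keep_min:
        raise ValueError("keep_max must exceed keep_min")
    native = spectra.grid.values
    n_out = int(np.floor((keep_max - keep_min) / increment + 1e-9)) + 1
    new_grid = keep_min + increment * np.arange(n_out)
    if new_grid[0] < native[0] - 1e-9 or new_grid[-1] > native[-1] + 1e-9:
        raise ValueError(
            f"requested range [{new_grid[0]}, {new_grid[-1]}] exceeds native "
            f"support [{native[0]}, {native[-1]}]"
        )
    out = np.empty((spectra.n_samples, n_out))
    for i in range(spectra.n_samples):
        out[i] = np.interp(new_grid, native, spectra.values[i])
    return SpectrumSet(
        grid=SpectralGrid(spectra.grid.axis_kind, new_grid),
        values=out,
        unit=spectra.unit,
        sample_ids=spectra.sample_ids.copy(),
        series_label=spectra.series_label,
    )


def average_sets(sets: list[SpectrumSet]) -> SpectrumSet:
    """Element-wise mean of spectrum sets aligned by sample id.

    All sets must share the grid, the unit and the same set of sample
    ids; rows are aligned to the first set's id order.  The returned
    series label is ``"AVG"``.
    """
    if len(sets) == 0:
        raise ValueError("need at least one SpectrumSet")
    first = sets[0]
    acc = np.zeros_like(first.values)
    for s in sets:
        if s.grid != first.grid:
            raise ValueError("grids differ between sets")
        if s.unit != first.unit:
            raise ValueError("units differ between sets")
        if s.n_samples != first.n_samples or set(s.sample_ids) != set(first.sample_ids):
            raise ValueError("sample ids differ between sets")
        if np.array_equal(s.sample_ids, first.sample_ids):
            acc += s.values
        else:
            order = {sid: i for i, sid in enumerate(s.sample_ids)}
            idx = np.array([order[sid] for sid in first.sample_ids])
            acc += s.values[idx]
    return SpectrumSet(
        grid=first.grid,
        values=acc / len(sets),
        unit=first.unit,
        sample_ids=first.sample_ids.copy(),
        series_label="AVG",
    )


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a spectral PCA."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray


def pca_scores(spectra: SpectrumSet, n_components: int) -> PCAResult:
    """PCA scores of column-mean-centered absorbance spectra.

    Components are the leading right singular vectors of the centered
    data; each loading vector is oriented so its largest-magnitude
    element is positive, which fixes the sign indeterminacy.
    """
    if spectra.unit != ABSORBANCE:
        raise ValueError("PCA expects absorbance spectra")
    X = spectra.values - spectra.values.mean(axis=0)
    n = X.shape[0]
    if not (1 <= n_components <= n):
        raise ValueError("n_components out of range")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]
    for j in range(n_components):
        k = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, k] < 0:
            loadings[j] = -loadings[j]
            scores[:, j] = -scores[:, j]
    total_var = (s**2).sum()
    evr = s[:n_components] ** 2 / total_var
    return PCAResult(scores=scores, loadings=loadings, explained_variance_ratio=evr)
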