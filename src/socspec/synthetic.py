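"""Synthetic cohort generator for the triplicate SOC spectroscopy design.

Emulates a 75-sample agricultural topsoil set drawn from three geological
parent-material strata (Devonian clay schists, Rotliegend silt/fine
sandstones, Jurassic sandstones; 25 samples each), with

* latent true SOC per sample, truncated-normal within each stratum;
* triplicate dry-combustion laboratory SOC series with heteroscedastic
  random error (SD rising with SOC) and one upward-biased laboratory;
* triplicate VNIR (350-2500 nm) and MIR (4000-650 cm^-1) reflectance
  series, each delivered spectrum the mean of two replicate scans.

The spectral forward model is Gaussian absorption bands on a smooth
baseline with linear mixing: band amplitudes scale with the sample's
organic / clay / quartz drivers.  MIR bands are narrow and diagnostic;
VNIR bands are broad and overlapping, and VNIR carries larger
sample-level baseline nuisance, which is what makes MIR calibrations
both more accurate and more stable downstream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .spectra import (
    REFLECTANCE,
    WAVELENGTH_NM,
    WAVENUMBER_CM,
    SpectralGrid,
    SpectrumSet,
)

logger = logging.getLogger(__name__)

VNIR = "vnir"
MIR = "mir"
_DOMAIN_INDEX = {VNIR: 0, MIR: 1}

# sub-stream tags for the master seed (stable; adding series or
# replicates never perturbs draws of earlier ones)
_TAG_COHORT = 1
_TAG_LAB = 2
_TAG_SAMPLE_FX = 3
_TAG_SERIES_FX = 4
_TAG_REPLICATE = 5


def _rng(master_seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, tags)]))


@dataclass(frozen=True)
class Stratum:
    name: str
    n: int
    soc_mean: float  # g/kg
    soc_sd: float  # g/kg
    clay_share_mean: float = 0.35  # clay fraction of the mineral part
    clay_share_sd: float = 0.05


@dataclass(frozen=True)
class DomainNoise:
    """Noise scales of one spectral domain (reflectance units unless noted)."""

    replicate_sd: float  # white noise per replicate scan
    sample_offset_sd: float  # per-sample baseline offset (nuisance)
    sample_slope_sd: float  # per-sample baseline tilt (nuisance)
    series_gain_sd: float  # per-series multiplicative gain spread
    series_offset_sd: float  # per-series smooth additive drift
    organic_strength_sd: float = 0.0  # extra per-sample relative spread of the
    # organic band strength in this domain: nonspecificity of the domain's
    # carbon features (large for broad overlapping VNIR bands, ~0 for the
    # diagnostic MIR fundamentals)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the triplicate design the analysis assumes:
    75 samples in three strata of 25 with stratum SOC means 26.2 / 10.2 /
    14.7 g/kg, SOC bounded to [6.18, 35.54] g/kg, three laboratory series
    with replicate SD rising from 0.21 g/kg (SOC = 10) to 0.65 g/kg
    (SOC = 25) and a +0.64 g/kg bias on the third series, and three
    spectral series per domain, each averaged from two replicate scans.
    """

    n_samples: int = 75
    strata: tuple[Stratum, ...] = (
        Stratum("Devonian", 25, 26.2, 4.5, clay_share_mean=0.55),
        Stratum("Rotliegend", 25, 10.2, 2.0, clay_share_mean=0.35),
        Stratum("Jurassic", 25, 14.7, 3.5, clay_share_mean=0.15),
    )
    soc_bounds: tuple[float, float] = (6.18, 35.54)
    n_lab_series: int = 3
    lab_bias: tuple[float, ...] = (0.0, 0.0, 0.64)
    lab_sd_low: float = 0.21  # replicate SD at the low SOC anchor
    lab_sd_high: float = 0.65  # replicate SD at the high SOC anchor
    soc_anchor_low: float = 10.0
    soc_anchor_high: float = 25.0
    n_spec_series: int = 3
    n_replicates: int = 2
    organic_absorptivity_sd: float = 0.03  # sample-level relative band-strength spread
    vnir_noise: DomainNoise = DomainNoise(
        replicate_sd=1.0e-3,
        sample_offset_sd=2.0e-2,
        sample_slope_sd=2.0e-2,
        series_gain_sd=3.0e-3,
        series_offset_sd=1.5e-3,
        organic_strength_sd=0.16,
    )
    mir_noise: DomainNoise = DomainNoise(
        replicate_sd=2.0e-3,
        sample_offset_sd=6.0e-3,
        sample_slope_sd=6.0e-3,
        series_gain_sd=3.0e-3,
        series_offset_sd=1.5e-3,
    )
    master_seed: int = 20220402

    def __post_init__(self) -> None:
        if sum(s.n for s in self.strata) != self.n_samples:
            raise ValueError("strata counts must sum to n_samples")
        lo, hi = self.soc_bounds
        if not lo < hi:
            raise ValueError("soc_bounds min must be < max")
        if any(s.soc_sd < 0 for s in self.strata):
            raise ValueError("stratum SOC SD must be >= 0")
        if self.lab_sd_low <= 0 or self.lab_sd_high <= 0:
            raise ValueError("lab SD anchors must be > 0")
        if len(self.lab_bias) != self.n_lab_series:
            raise ValueError("one lab bias per laboratory series required")
        if self.n_replicates < 1 or self.n_spec_series < 1:
            raise ValueError("need at least one spectral series and replicate")

    def noise(self, domain: str) -> DomainNoise:
        return self.vnir_noise if domain == VNIR else self.mir_noise

    def to_yaml(self, path) -> None:
        d = {
            "n_samples": self.n_samples,
            "strata": [
                {
                    "name": s.name,
                    "n": s.n,
                    "soc_mean": s.soc_mean,
                    "soc_sd": s.soc_sd,
                    "clay_share_mean": s.clay_share_mean,
                    "clay_share_sd": s.clay_share_sd,
                }
                for s in self.strata
            ],
            "soc_bounds": list(self.soc_bounds),
            "n_lab_series": self.n_lab_series,
            "lab_bias": list(self.lab_bias),
            "lab_sd_low": self.lab_sd_low,
            "lab_sd_high": self.lab_sd_high,
            "soc_anchor_low": self.soc_anchor_low,
            "soc_anchor_high": self.soc_anchor_high,
            "n_spec_series": self.n_spec_series,
            "n_replicates": self.n_replicates,
            "organic_absorptivity_sd": self.organic_absorptivity_sd,
            "vnir_noise": vars(self.vnir_noise) | {},
            "mir_noise": vars(self.mir_noise) | {},
            "master_seed": self.master_seed,
        }
        d["vnir_noise"] = dict(self.vnir_noise.__dict__)
        d["mir_noise"] = dict(self.mir_noise.__dict__)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["strata"] = tuple(Stratum(**s) for s in d["strata"])
        d["soc_bounds"] = tuple(d["soc_bounds"])
        d["lab_bias"] = tuple(d["lab_bias"])
        d["vnir_noise"] = DomainNoise(**d["vnir_noise"])
        d["mir_noise"] = DomainNoise(**d["mir_noise"])
        return cls(**d)


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: depth = amplitude * driver strength."""

    center: float  # native grid units
    width: float  # Gaussian sigma, native grid units
    amplitude: float  # reflectance depth at full driver strength
    driver: str  # organic | clay | quartz | baseline


@dataclass(frozen=True)
class EndmemberLibrary:
    """Per-domain absorption band lists for the forward model.

    MIR bands are narrow relative to the grid span (diagnostic organic,
    clay-mineral and quartz features); VNIR bands are broad and
    overlapping, as in real soil reflectance.
    """

    vnir: tuple[Band, ...]
    mir: tuple[Band, ...]

    def bands(self, domain: str) -> tuple[Band, ...]:
        return self.vnir if domain == VNIR else self.mir

    def validate(self, grids: dict[str, SpectralGrid]) -> None:
        for domain, bands in ((VNIR, self.vnir), (MIR, self.mir)):
            g = grids[domain].values
            for b in bands:
                if not (g[0] <= b.center <= g[-1]):
                    raise ValueError(f"{domain} band center {b.center} outside grid")
                if b.width <= 0:
                    raise ValueError("band widths must be > 0")
        vnir_span = grids[VNIR].values[-1] - grids[VNIR].values[0]
        mir_span = grids[MIR].values[-1] - grids[MIR].values[0]
        if max(b.width for b in self.mir) / mir_span >= min(b.width for b in self.vnir) / vnir_span:
            raise ValueError("MIR bands must be narrower than VNIR bands relative to span")


def default_library() -> EndmemberLibrary:
    """Default band library.

    MIR: organic C-H features near 2950-2870 cm^-1, clay-mineral O-H
    near 3600-3700 cm^-1 and quartz overtones near 2000-1790 and
    1280-1070 cm^-1.  VNIR: broad organic darkening in the visible and
    broad water/hydroxyl features near 1415, 1915 and 2210 nm.
    """
    return EndmemberLibrary(
        vnir=(
            Band(600.0, 220.0, 0.16, "organic"),
            Band(1100.0, 260.0, 0.05, "organic"),
            Band(2300.0, 120.0, 0.04, "organic"),
            Band(1415.0, 45.0, 0.05, "clay"),
            Band(1915.0, 60.0, 0.12, "clay"),
            Band(2207.0, 45.0, 0.07, "clay"),
            Band(1300.0, 420.0, 0.03, "quartz"),
        ),
        mir=(
            Band(2925.0, 20.0, 0.10, "organic"),
            Band(2870.0, 16.0, 0.07, "organic"),
            Band(1720.0, 25.0, 0.05, "organic"),
            Band(3650.0, 22.0, 0.14, "clay"),
            Band(3620.0, 16.0, 0.09, "clay"),
            Band(915.0, 30.0, 0.06, "clay"),
            Band(1895.0, 40.0, 0.11, "quartz"),
            Band(1790.0, 30.0, 0.07, "quartz"),
            Band(1175.0, 45.0, 0.13, "quartz"),
            Band(1080.0, 35.0, 0.09, "quartz"),
        ),
    )


def native_grids() -> dict[str, SpectralGrid]:
    """Native instrument grids: VNIR 350-2500 nm @ 1 nm, MIR 650-4000 cm^-1 @ 2 cm^-1."""
    return {
        VNIR: SpectralGrid(WAVELENGTH_NM, np.arange(350.0, 2500.0 + 0.5, 1.0)),
        MIR: SpectralGrid(WAVENUMBER_CM, np.arange(650.0, 4000.0 + 1.0, 2.0)),
    }


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection sampler for a truncated normal; errors if acceptance < 1%."""
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ValueError("degenerate draw with mean outside bounds")
        return np.full(size, float(mean))
    out = np.empty(0)
    n_drawn = 0
    while out.size < size:
        batch = rng.normal(mean, sd, size=max(4 * size, 128))
        n_drawn += batch.size
        out = np.concatenate([out, batch[(batch >= lo) & (batch <= hi)]])
        if n_drawn >= 10_000 and out.size / n_drawn < 0.01:
            raise ValueError(
                f"truncation acceptance below 1% for mean={mean}, sd={sd}, "
                f"bounds=({lo}, {hi})"
            )
    return out[:size]


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate the sample frame: ids, strata, latent SOC and composition.

    Returns a DataFrame with columns ``sample_id, stratum, soc_true,
    frac_clay, frac_quartz, frac_organic, organic_absorptivity``.  SOC is
    truncated-normal within each stratum; the mineral part is split into
    clay and quartz with stratum-specific clay shares so strata are
    spectrally separable.  ``organic_absorptivity`` is a sample-level
    multiplier on the organic band strength (spread
    ``organic_absorptivity_sd``), shared by both spectral domains.
    """
    rng = _rng(config.master_seed, _TAG_COHORT)
    lo, hi = config.soc_bounds
    rows = []
    idx = 1
    for stratum in config.strata:
        soc = _truncated_normal(rng, stratum.soc_mean, stratum.soc_sd, lo, hi, stratum.n)
        clay_share = np.clip(
            rng.normal(stratum.clay_share_mean, stratum.clay_share_sd, stratum.n),
            0.02,
            0.95,
        )
        absorptivity = np.clip(
            rng.normal(1.0, config.organic_absorptivity_sd, stratum.n), 0.5, 1.5
        )
        for i in range(stratum.n):
            frac_org = soc[i] / 500.0  # g/kg carbon -> rough OM volume fraction
            frac_clay = clay_share[i] * (1.0 - frac_org)
            frac_quartz = 1.0 - frac_org - frac_clay
            rows.append(
                {
                    "sample_id": f"S{idx:03d}",
                    "stratum": stratum.name,
                    "soc_true": soc[i],
                    "frac_clay": frac_clay,
                    "frac_quartz": frac_quartz,
                    "frac_organic": frac_org,
                    "organic_absorptivity": absorptivity[i],
                }
            )
            idx += 1
    frame = pd.DataFrame(rows)
    assert np.allclose(
        frame[["frac_clay", "frac_quartz", "frac_organic"]].sum(axis=1), 1.0, atol=1e-9
    )
    return frame


def lab_error_sd(soc: np.ndarray, config: SimConfig) -> np.ndarray:
    """Replicate-error SD as a function of SOC: linear between the two
    anchor points, constant outside them."""
    return np.interp(
        np.asarray(soc, dtype=float),
        [config.soc_anchor_low, config.soc_anchor_high],
        [config.lab_sd_low, config.lab_sd_high],
    )


def generate_lab_measurements(samples: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Triplicate laboratory SOC series with heteroscedastic error.

    Each series k reports ``soc_true + bias_k + eps`` with
    ``eps ~ N(0, sd(soc_true))``; values are floored at 0.  Returns a
    reference table with columns ``sample_id, stratum, lab_1..lab_K,
    lab_avg`` (the across-series mean).
    """
    soc = samples["soc_true"].to_numpy()
    sd = lab_error_sd(soc, config)
    table = samples[["sample_id", "stratum"]].copy()
    cols = []
    for k in range(config.n_lab_series):
        rng = _rng(config.master_seed, _TAG_LAB, k)
        vals = soc + config.lab_bias[k] + rng.normal(0.0, 1.0, soc.size) * sd
        col = f"lab_{k + 1}"
        table[col] = np.maximum(vals, 0.0)
        cols.append(col)
    table["lab_avg"] = table[cols].mean(axis=1)
    return table


def _gaussian(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def _baseline(domain: str, u: np.ndarray) -> np.ndarray:
    # smooth, gently curved reflectance continuum; u in [0, 1] along the grid
    if domain == VNIR:
        return 0.45 + 0.18 * u - 0.06 * u**2
    return 0.55 + 0.05 * u - 0.02 * u**2


def _driver_strengths(samples: pd.DataFrame, config: SimConfig) -> dict[str, np.ndarray]:
    soc_hi = config.soc_bounds[1]
    return {
        "organic": (samples["soc_true"].to_numpy() / soc_hi)
        * samples["organic_absorptivity"].to_numpy(),
        "clay": samples["frac_clay"].to_numpy(),
        "quartz": samples["frac_quartz"].to_numpy(),
        "baseline": np.ones(len(samples)),
    }


def _clean_spectra(
    samples: pd.DataFrame,
    library: EndmemberLibrary,
    config: SimConfig,
    domain: str,
    grid: SpectralGrid,
) -> np.ndarray:
    """Noise-free reflectance: baseline minus linearly mixed Gaussian bands,
    plus the per-sample baseline nuisance (offset and tilt)."""
    x = grid.values
    u = (x - x[0]) / (x[-1] - x[0])
    strengths = _driver_strengths(samples, config)
    spectra = np.tile(_baseline(domain, u), (len(samples), 1))
    for band in library.bands(domain):
        shape = _gaussian(x, band.center, band.width)
        spectra -= np.outer(strengths[band.driver] * band.amplitude, shape)
    noise = config.noise(domain)
    fx_rng = _rng(config.master_seed, _TAG_SAMPLE_FX, _DOMAIN_INDEX[domain])
    offset = fx_rng.normal(0.0, 1.0, len(samples)) * noise.sample_offset_sd
    slope = fx_rng.normal(0.0, 1.0, len(samples)) * noise.sample_slope_sd
    spectra += offset[:, None] + np.outer(slope, u - 0.5)
    if noise.organic_strength_sd > 0:
        factor = np.clip(
            1.0 + fx_rng.normal(0.0, 1.0, len(samples)) * noise.organic_strength_sd,
            0.2,
            None,
        )
        extra = factor - 1.0  # add (factor-1) * organic contribution on top
        for band in library.bands(domain):
            if band.driver == "organic":
                shape = _gaussian(x, band.center, band.width)
                spectra -= np.outer(
                    extra * strengths["organic"] * band.amplitude, shape
                )
    return spectra


@dataclass
class SpectralSeriesSet:
    """Generated spectral series: per domain the replicate-averaged series
    1..K, plus the un-averaged replicate scans for repeatability work."""

    series: dict[str, list[SpectrumSet]]
    replicates: dict[tuple[str, int], list[SpectrumSet]]
    n_clipped: dict[str, int]

    def averaged(self, domain: str) -> list[SpectrumSet]:
        return self.series[domain]


def generate_spectral_series(
    samples: pd.DataFrame,
    library: EndmemberLibrary | None = None,
    config: SimConfig | None = None,
) -> SpectralSeriesSet:
    """Generate triplicate VNIR and MIR reflectance series.

    Each series applies its own smooth gain/offset perturbation; each of
    the ``n_replicates`` replicate scans adds white noise; the delivered
    series spectrum is the replicate mean.  Reflectance leaving (0, 1]
    is clipped, with a logged count.  Deterministic given
    ``config.master_seed``.
    """
    config = config or SimConfig()
    library = library or default_library()
    grids = native_grids()
    library.validate(grids)
    series: dict[str, list[SpectrumSet]] = {VNIR: [], MIR: []}
    replicates: dict[tuple[str, int], list[SpectrumSet]] = {}
    n_clipped = {VNIR: 0, MIR: 0}
    ids = samples["sample_id"].to_numpy()
    for domain in (VNIR, MIR):
        grid = grids[domain]
        x = grid.values
        u = (x - x[0]) / (x[-1] - x[0])
        clean = _clean_spectra(samples, library, config, domain, grid)
        noise = config.noise(domain)
        for s in range(config.n_spec_series):
            srng = _rng(config.master_seed, _TAG_SERIES_FX, _DOMAIN_INDEX[domain], s)
            gain = 1.0 + srng.normal(0.0, 1.0) * noise.series_gain_sd
            a0, a1 = srng.normal(0.0, 1.0, 2) * noise.series_offset_sd
            perturbed = gain * clean + a0 + a1 * (u - 0.5)
            reps = []
            for r in range(config.n_replicates):
                rrng = _rng(
                    config.master_seed, _TAG_REPLICATE, _DOMAIN_INDEX[domain], s, r
                )
                vals = perturbed + rrng.normal(0.0, 1.0, perturbed.shape) * noise.replicate_sd
                n_out = int(((vals <= 0) | (vals > 1)).sum())
                if n_out:
                    n_clipped[domain] += n_out
                    vals = np.clip(vals, 1e-6, 1.0)
                reps.append(
                    SpectrumSet(
                        grid=grid,
                        values=vals,
                        unit=REFLECTANCE,
                        sample_ids=ids.copy(),
                        series_label=f"{domain.upper()}_{s + 1}_rep{r + 1}",
                    )
                )
            replicates[(domain, s)] = reps
            mean_vals = np.mean([r.values for r in reps], axis=0)
            series[domain].append(
                SpectrumSet(
                    grid=grid,
                    values=mean_vals,
                    unit=REFLECTANCE,
                    sample_ids=ids.copy(),
                    series_label=f"{domain.upper()}_{s + 1}",
                )
            )
    total_clip = sum(n_clipped.values())
    if total_clip:
        logger.warning("clipped %d reflectance values to (0, 1]", total_clip)
    return SpectralSeriesSet(series=series, replicates=replicates, n_clipped=n_clipped)
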