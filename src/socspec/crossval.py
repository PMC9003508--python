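"""Repeated stratified nested Monte-Carlo cross-validation and the
source-swap experiment grids.

The outer loop redraws m stratified folds (stratified on soil
parent-material) in each of k repetitions.  Within a repetition, a PLSR
model is calibrated on m-1 folds — on square-root transformed SOC, with
the number of latent variables chosen by internal leave-one-out CV
(minimum RMSE) — and predicts the held-out fold from the *validation*
spectra source, so that calibration and validation spectra (or
reference series) can come from different measurement series.  The n
held-out predictions of one repetition are pooled and scored against
the validation reference; metrics are aggregated as mean and SD over
repetitions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plsr import fit_plsr, max_components, predict, select_n_latent_loo
from .spectra import SpectrumSet

_TAG_FOLDS = 11

METRIC_COLUMNS = ["rmse", "r2", "bias", "rpd", "rpiq", "r2_ss"]


@dataclass(frozen=True)
class CVConfig:
    """Monte-Carlo cross-validation settings.

    ``n_repetitions`` random stratified fold draws (default 100),
    ``n_folds`` folds (default 3), square-root response transform by
    default, ``max_latent`` candidate latent variables (default 20,
    capped at n_cal - 2 for the internal leave-one-out loop).
    """

    n_repetitions: int = 100
    n_folds: int = 3
    transform: str = "sqrt"  # "sqrt" | "none"
    max_latent: int = 20
    master_seed: int = 1

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.n_repetitions < 1:
            raise ValueError("need at least 1 repetition")
        if self.transform not in ("sqrt", "none"):
            raise ValueError("transform must be 'sqrt' or 'none'")


@dataclass
class FoldPlan:
    """Fold assignments: one row per repetition, one column per sample."""

    sample_ids: np.ndarray  # (n,)
    assignments: np.ndarray  # (n_reps, n) integer fold index

    @property
    def n_repetitions(self) -> int:
        return int(self.assignments.shape[0])

    @property
    def n_folds(self) -> int:
        return int(self.assignments.max()) + 1


def stratified_folds(samples: pd.DataFrame, config: CVConfig) -> FoldPlan:
    """Draw ``n_repetitions`` stratified random fold partitions.

    Every stratum is split as evenly as possible across folds; leftover
    samples go to the currently smallest folds (ties rotated by
    repetition and stratum) so fold totals differ by at most one.
    Deterministic given ``config.master_seed``.
    """
    if "stratum" not in samples.columns:
        raise ValueError("samples need a 'stratum' column")
    ids = samples["sample_id"].to_numpy()
    strata = samples["stratum"].to_numpy()
    stratum_names = list(pd.unique(strata))
    k = config.n_folds
    for name in stratum_names:
        if (strata == name).sum() < k:
            warnings.warn(
                f"stratum {name!r} has fewer samples than folds; spreading as evenly as possible"
            )
    assignments = np.empty((config.n_repetitions, ids.size), dtype=int)
    for rep in range(config.n_repetitions):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.master_seed), _TAG_FOLDS, rep])
        )
        fold_sizes = np.zeros(k, dtype=int)
        for s_idx, name in enumerate(stratum_names):
            members = np.flatnonzero(strata == name)
            rng.shuffle(members)
            base = members.size // k
            rem = members.size % k
            # fill every fold with the base share first
            counts = np.full(k, base)
            if rem:
                # leftovers go to the currently smallest folds; ties are
                # rotated by repetition and stratum so no fold is favoured
                tiebreak = (np.arange(k) - rep - s_idx) % k
                order = np.lexsort((tiebreak, fold_sizes + counts))
                counts[order[:rem]] += 1
            pos = 0
            for f in range(k):
                assignments[rep, members[pos : pos + counts[f]]] = f
                pos += counts[f]
            fold_sizes += counts
    return FoldPlan(sample_ids=ids.copy(), assignments=assignments)


@dataclass
class CVResult:
    """Outcome of one repeated nested cross-validation run."""

    sample_ids: np.ndarray
    predictions: np.ndarray  # (n_reps, n) pooled validation predictions
    metrics: pd.DataFrame  # per repetition
    n_latent: np.ndarray  # (n_reps, n_folds) chosen component counts
    n_clamped: int  # negative sqrt-scale predictions clamped to 0

    @property
    def metric_mean(self) -> pd.Series:
        return self.metrics.mean()

    @property
    def metric_sd(self) -> pd.Series:
        return self.metrics.std(ddof=1) if len(self.metrics) > 1 else self.metrics.iloc[0] * 0.0

    def per_sample(self) -> pd.DataFrame:
        """Mean and SD of each sample's prediction over repetitions."""
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "pred_mean": self.predictions.mean(axis=0),
                "pred_sd": self.predictions.std(axis=0, ddof=1)
                if self.predictions.shape[0] > 1
                else np.zeros(self.predictions.shape[1]),
            }
        )


def performance_metrics(reference: np.ndarray, predicted: np.ndarray) -> dict[str, float]:
    """RMSE, R^2 (squared Pearson), bias, RPD, RPIQ and 1-SSE/SST R^2.

    bias = mean(predicted - reference); RPD = SD(reference)/RMSE and
    RPIQ = IQR(reference)/RMSE.  A zero RMSE yields infinite RPD/RPIQ.
    """
    y = np.asarray(reference, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size != yhat.size or y.size < 3:
        raise ValueError("need equally long vectors with n >= 3")
    resid = yhat - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    bias = float(np.mean(resid))
    r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2) if np.std(yhat) > 0 else 0.0
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_ss = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else float("nan")
    sd_y = float(np.std(y, ddof=1))
    iqr_y = float(np.percentile(y, 75) - np.percentile(y, 25))
    rpd = sd_y / rmse if rmse > 0 else float("inf")
    rpiq = iqr_y / rmse if rmse > 0 else float("inf")
    return {"rmse": rmse, "r2": r2, "bias": bias, "rpd": rpd, "rpiq": rpiq, "r2_ss": r2_ss}


def _aligned_matrix(spectra: SpectrumSet, sample_ids: np.ndarray) -> np.ndarray:
    pos = {sid: i for i, sid in enumerate(spectra.sample_ids)}
    try:
        idx = np.array([pos[sid] for sid in sample_ids])
    except KeyError as e:
        raise ValueError(f"sample {e.args[0]!r} missing from spectra") from None
    return spectra.values[idx]


def _aligned_reference(ref, sample_ids: np.ndarray) -> np.ndarray:
    if isinstance(ref, pd.Series):
        try:
            return ref.loc[sample_ids].to_numpy(dtype=float)
        except KeyError:
            raise ValueError("reference series missing some sample ids") from None
    arr = np.asarray(ref, dtype=float)
    if arr.size != sample_ids.size:
        raise ValueError("reference length does not match sample count")
    return arr


def nested_mccv(
    cal_spectra: SpectrumSet,
    val_spectra: SpectrumSet,
    cal_ref,
    val_ref,
    plan: FoldPlan,
    config: CVConfig,
) -> CVResult:
    """Repeated nested Monte-Carlo CV with possibly distinct calibration
    and validation sources.

    Per repetition and fold: fit PLSR on the calibration spectra and
    (transformed) calibration reference of the training folds, with the
    component count selected by internal leave-one-out CV, then predict
    the held-out fold from the validation spectra.  Predictions are
    back-transformed (negative square-root-scale values clamped to zero
    before squaring, counted) and pooled so every sample is validated
    exactly once per repetition; metrics are scored against the
    validation reference.
    """
    if cal_spectra.grid != val_spectra.grid:
        raise ValueError("calibration and validation spectra must share a grid")
    ids = plan.sample_ids
    Xcal = _aligned_matrix(cal_spectra, ids)
    Xval = _aligned_matrix(val_spectra, ids)
    y_cal = _aligned_reference(cal_ref, ids)
    y_val = _aligned_reference(val_ref, ids)
    if config.transform == "sqrt":
        if (y_cal < 0).any():
            raise ValueError("sqrt transform requires non-negative calibration reference")
        y_fit = np.sqrt(y_cal)
    else:
        y_fit = y_cal
    n = ids.size
    n_reps = plan.n_repetitions
    k = plan.n_folds
    preds = np.empty((n_reps, n))
    chosen = np.empty((n_reps, k), dtype=int)
    n_clamped = 0
    rows = []
    for rep in range(n_reps):
        assign = plan.assignments[rep]
        pooled = np.empty(n)
        for f in range(k):
            val_idx = assign == f
            cal_idx = ~val_idx
            Xtr = Xcal[cal_idx]
            ytr = y_fit[cal_idx]
            cap = min(config.max_latent, Xtr.shape[0] - 2, Xtr.shape[1])
            try:
                a, _ = select_n_latent_loo(Xtr, ytr, cap)
            except ValueError as e:
                raise ValueError(f"LOO selection failed in repetition {rep}, fold {f}: {e}")
            model = fit_plsr(Xtr, ytr, a)
            raw = predict(model, Xval[val_idx])
            if config.transform == "sqrt":
                n_clamped += int((raw < 0).sum())
                raw = np.clip(raw, 0.0, None) ** 2
            pooled[val_idx] = raw
            chosen[rep, f] = a
        preds[rep] = pooled
        rows.append(performance_metrics(y_val, pooled))
    metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    return CVResult(
        sample_ids=ids.copy(),
        predictions=preds,
        metrics=metrics,
        n_latent=chosen,
        n_clamped=n_clamped,
    )


@dataclass
class ExperimentGrid:
    """Source-swap grid: one nested CV per (calibration, validation) pair,
    all sharing one fold plan so cell contrasts reflect the data sources."""

    mode: str
    cal_labels: list[str]
    val_labels: list[str]
    cells: dict[tuple[str, str], CVResult]

    def metric_table(self, metric: str = "rmse", stat: str = "mean") -> pd.DataFrame:
        out = pd.DataFrame(index=self.cal_labels, columns=self.val_labels, dtype=float)
        for (c, v), res in self.cells.items():
            out.loc[c, v] = (
                res.metric_mean[metric] if stat == "mean" else res.metric_sd[metric]
            )
        return out

    def formatted(self, metric: str = "rmse") -> pd.DataFrame:
        """Cells as 'mean (±2 SD)' strings, the conventional report layout."""
        mean = self.metric_table(metric, "mean")
        sd = self.metric_table(metric, "sd")
        out = mean.copy().astype(object)
        for c in self.cal_labels:
            for v in self.val_labels:
                out.loc[c, v] = f"{mean.loc[c, v]:.2f} (±{2 * sd.loc[c, v]:.2f})"
        return out


def run_source_grid(
    samples: pd.DataFrame,
    spectra_sources: dict[str, SpectrumSet],
    ref_sources: dict[str, pd.Series],
    mode: str,
    config: CVConfig,
    plan: FoldPlan | None = None,
) -> ExperimentGrid:
    """Run the full swap experiment over calibration x validation sources.

    ``mode="swap-spectra"`` varies the spectral series on both axes with a
    single fixed reference source; ``mode="swap-reference"`` varies the
    laboratory reference series with a single fixed spectra source.  All
    cells share one FoldPlan.
    """
    if mode == "swap-spectra":
        if len(ref_sources) != 1:
            raise ValueError("swap-spectra mode requires exactly one reference source")
        labels = list(spectra_sources)
    elif mode == "swap-reference":
        if len(spectra_sources) != 1:
            raise ValueError("swap-reference mode requires exactly one spectra source")
        labels = list(ref_sources)
    else:
        raise ValueError("mode must be 'swap-spectra' or 'swap-reference'")
    if plan is None:
        plan = stratified_folds(samples, config)
    cells: dict[tuple[str, str], CVResult] = {}
    for cal in labels:
        for val in labels:
            if mode == "swap-spectra":
                ref = next(iter(ref_sources.values()))
                res = nested_mccv(
                    spectra_sources[cal], spectra_sources[val], ref, ref, plan, config
                )
            else:
                spec = next(iter(spectra_sources.values()))
                res = nested_mccv(
                    spec, spec, ref_sources[cal], ref_sources[val], plan, config
                )
            cells[(cal, val)] = res
    return ExperimentGrid(mode=mode, cal_labels=labels, val_labels=labels, cells=cells)
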