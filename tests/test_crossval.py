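"""Stratified Monte-Carlo fold plans, the nested CV engine, validation
metrics and the source-swap grids."""
import numpy as np
import pandas as pd
import pytest

from socspec import (
    CVConfig,
    SpectralGrid,
    SpectrumSet,
    nested_mccv,
    performance_metrics,
    run_source_grid,
    stratified_folds,
)
from socspec.spectra import ABSORBANCE, WAVELENGTH_NM


@pytest.fixture(scope="module")
def linear_spectra(cohort):
    """Noise-free spectra exactly linear in sqrt(SOC): 12 channels whose
    rows are sqrt(soc) * direction + baseline."""
    rng = np.random.default_rng(15)
    direction = rng.normal(size=12)
    baseline = rng.normal(size=12)
    vals = np.sqrt(cohort["soc_true"].to_numpy())[:, None] * direction + baseline
    return SpectrumSet(
        grid=SpectralGrid(WAVELENGTH_NM, np.arange(400.0, 412.0)),
        values=vals,
        unit=ABSORBANCE,
        sample_ids=cohort["sample_id"].to_numpy(),
        series_label="linear",
    )


def test_default_fold_plan_balances_strata(cohort):
    cfg = CVConfig(n_repetitions=10, n_folds=3, master_seed=2)
    plan = stratified_folds(cohort, cfg)
    strata = cohort.set_index("sample_id")["stratum"]
    for rep in range(plan.n_repetitions):
        assign = plan.assignments[rep]
        sizes = np.bincount(assign, minlength=3)
        assert (sizes == 25).all()
        for name in strata.unique():
            counts = np.bincount(assign[strata.to_numpy() == name], minlength=3)
            assert counts.max() - counts.min() <= 1
            assert counts.sum() == 25


def test_leave_one_out_fold_layout(cohort):
    cfg = CVConfig(n_repetitions=1, n_folds=75, master_seed=3)
    with pytest.warns(UserWarning, match="fewer samples"):
        plan = stratified_folds(cohort, cfg)
    assign = plan.assignments[0]
    assert sorted(assign) == list(range(75))


def test_hundred_fold_plans_are_valid_and_distinct(cohort):
    cfg = CVConfig(n_repetitions=100, n_folds=3, master_seed=4)
    plan = stratified_folds(cohort, cfg)
    hashes = set()
    for rep in range(100):
        assign = plan.assignments[rep]
        assert np.bincount(assign, minlength=3).sum() == 75
        assert set(assign) == {0, 1, 2}
        hashes.add(assign.tobytes())
    assert len(hashes) >= 99


def test_fold_plans_are_deterministic(cohort):
    cfg = CVConfig(n_repetitions=5, master_seed=6)
    a = stratified_folds(cohort, cfg)
    b = stratified_folds(cohort, cfg)
    assert np.array_equal(a.assignments, b.assignments)


def test_metrics_identity_prediction():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    m = performance_metrics(y, y)
    assert m["rmse"] == 0.0 and m["bias"] == 0.0 and m["r2"] == pytest.approx(1.0)
    assert np.isinf(m["rpd"]) and np.isinf(m["rpiq"])


def test_metrics_constant_shift():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    m = performance_metrics(y, y + 1.0)
    assert m["rmse"] == pytest.approx(1.0)
    assert m["bias"] == pytest.approx(1.0)


def test_metrics_match_hand_computation():
    y = np.array([10.0, 12.0, 14.0, 16.0, 18.0])
    yhat = np.array([11.0, 11.5, 14.5, 15.0, 19.0])
    m = performance_metrics(y, yhat)
    resid = yhat - y
    assert m["rmse"] == pytest.approx(np.sqrt(np.mean(resid**2)))
    assert m["bias"] == pytest.approx(resid.mean())
    assert m["r2"] == pytest.approx(np.corrcoef(y, yhat)[0, 1] ** 2)
    assert m["rpd"] == pytest.approx(np.std(y, ddof=1) / m["rmse"])
    assert m["rpiq"] == pytest.approx(
        (np.percentile(y, 75) - np.percentile(y, 25)) / m["rmse"]
    )
    assert m["r2_ss"] == pytest.approx(1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2))


def test_one_repetition_pools_every_sample_once(cohort, linear_spectra, soc_true):
    cfg = CVConfig(n_repetitions=1, master_seed=8, max_latent=3)
    plan = stratified_folds(cohort, cfg)
    res = nested_mccv(linear_spectra, linear_spectra, soc_true, soc_true, plan, cfg)
    assert res.predictions.shape == (1, 75)
    assert np.isfinite(res.predictions).all()
    # every sample is in the validation set exactly once per repetition
    assert np.bincount(plan.assignments[0]).sum() == 75


def test_noiseless_identifiable_case_is_recovered(cohort, linear_spectra, soc_true):
    cfg = CVConfig(n_repetitions=2, master_seed=9, max_latent=3)
    plan = stratified_folds(cohort, cfg)
    res = nested_mccv(linear_spectra, linear_spectra, soc_true, soc_true, plan, cfg)
    assert res.metric_mean["rmse"] < 1e-6
    assert res.metric_mean["r2"] > 0.999


def test_nested_mccv_is_deterministic(cohort, linear_spectra, soc_true):
    cfg = CVConfig(n_repetitions=2, master_seed=10, max_latent=3)
    plan = stratified_folds(cohort, cfg)
    a = nested_mccv(linear_spectra, linear_spectra, soc_true, soc_true, plan, cfg)
    b = nested_mccv(linear_spectra, linear_spectra, soc_true, soc_true, plan, cfg)
    assert np.array_equal(a.predictions, b.predictions)
    pd.testing.assert_frame_equal(a.metrics, b.metrics)


def test_misaligned_inputs_raise(cohort, linear_spectra, soc_true):
    cfg = CVConfig(n_repetitions=1, master_seed=11, max_latent=3)
    plan = stratified_folds(cohort, cfg)
    short = linear_spectra.copy()
    short.sample_ids = short.sample_ids.copy()
    short.sample_ids[0] = "missing"
    with pytest.raises(ValueError, match="missing"):
        nested_mccv(short, linear_spectra, soc_true, soc_true, plan, cfg)


def test_single_source_grid_equals_plain_cv(cohort, linear_spectra, soc_true):
    cfg = CVConfig(n_repetitions=1, master_seed=12, max_latent=3)
    plan = stratified_folds(cohort, cfg)
    grid = run_source_grid(
        cohort, {"S": linear_spectra}, {"ref": soc_true}, "swap-spectra", cfg, plan=plan
    )
    direct = nested_mccv(linear_spectra, linear_spectra, soc_true, soc_true, plan, cfg)
    assert grid.metric_table("rmse").shape == (1, 1)
    assert grid.cells[("S", "S")].metric_mean["rmse"] == pytest.approx(
        direct.metric_mean["rmse"]
    )


def test_swap_reference_with_identical_unbiased_labs_is_exchangeable(
    cohort, linear_spectra, soc_true
):
    """With zero lab noise and no bias every reference source coincides, so
    every grid cell must coincide too."""
    cfg = CVConfig(n_repetitions=2, master_seed=13, max_latent=3)
    plan = stratified_folds(cohort, cfg)
    refs = {"lab_1": soc_true, "lab_2": soc_true.copy()}
    grid = run_source_grid(
        cohort, {"S": linear_spectra}, refs, "swap-reference", cfg, plan=plan
    )
    rmse = grid.metric_table("rmse").to_numpy()
    assert np.allclose(rmse, rmse[0, 0], atol=1e-9)


def test_grid_mode_validation(cohort, linear_spectra, soc_true):
    cfg = CVConfig(n_repetitions=1, master_seed=14)
    with pytest.raises(ValueError, match="exactly one reference"):
        run_source_grid(
            cohort,
            {"S": linear_spectra},
            {"a": soc_true, "b": soc_true},
            "swap-spectra",
            cfg,
        )
    with pytest.raises(ValueError, match="mode"):
        run_source_grid(cohort, {"S": linear_spectra}, {"a": soc_true}, "nonsense", cfg)


def test_formatted_grid_reports_mean_and_two_sd(cohort, linear_spectra, soc_true):
    cfg = CVConfig(n_repetitions=2, master_seed=16, max_latent=3)
    plan = stratified_folds(cohort, cfg)
    grid = run_source_grid(
        cohort, {"S": linear_spectra}, {"ref": soc_true}, "swap-spectra", cfg, plan=plan
    )
    cell = grid.formatted("rmse").loc["S", "S"]
    assert "(±" in cell
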