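"""Generator contracts: stratified cohort, heteroscedastic lab error,
triplicate spectra with the intended repeatability structure."""
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from socspec import (
    DomainNoise,
    SimConfig,
    Stratum,
    generate_cohort,
    generate_lab_measurements,
    generate_spectral_series,
    lab_error_sd,
)
from socspec.synthetic import MIR, VNIR


def quiet_noise():
    return DomainNoise(0.0, 0.0, 0.0, 0.0, 0.0, organic_strength_sd=0.0)


def test_default_cohort_counts_and_invariants(cohort, sim_config):
    assert len(cohort) == 75
    assert cohort.groupby("stratum").size().eq(25).all()
    lo, hi = sim_config.soc_bounds
    assert cohort["soc_true"].between(lo, hi).all()
    comp = cohort[["frac_clay", "frac_quartz", "frac_organic"]]
    assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-9)
    assert ((comp >= 0) & (comp <= 1)).all().all()


def test_degenerate_single_sample_draw():
    cfg = SimConfig(
        n_samples=1,
        strata=(Stratum("only", 1, 15.0, 0.0),),
        lab_bias=(0.0, 0.0, 0.0),
    )
    frame = generate_cohort(cfg)
    assert frame["soc_true"].iloc[0] == pytest.approx(15.0)


def test_infeasible_truncation_raises():
    cfg = SimConfig(
        n_samples=5,
        strata=(Stratum("off", 5, 100.0, 1.0),),
        lab_bias=(0.0, 0.0, 0.0),
    )
    with pytest.raises(ValueError, match="acceptance"):
        generate_cohort(cfg)


def test_stratum_means_match_truncated_normal_oracle():
    """Empirical stratum means at large n agree with the truncated-normal
    expectation (the configured mean corrected for the SOC bounds)."""
    strata = tuple(
        Stratum(s.name, 3400 if s.name == "Devonian" else 3300, s.soc_mean, s.soc_sd)
        for s in SimConfig().strata
    )
    cfg = SimConfig(n_samples=10_000, strata=strata, master_seed=5)
    frame = generate_cohort(cfg)
    lo, hi = cfg.soc_bounds
    for s in strata:
        a, b = (lo - s.soc_mean) / s.soc_sd, (hi - s.soc_mean) / s.soc_sd
        expected = stats.truncnorm.mean(a, b, loc=s.soc_mean, scale=s.soc_sd)
        se = stats.truncnorm.std(a, b, loc=s.soc_mean, scale=s.soc_sd) / np.sqrt(s.n)
        got = frame.loc[frame["stratum"] == s.name, "soc_true"].mean()
        assert got == pytest.approx(expected, abs=2 * se)
    means = frame.groupby("stratum")["soc_true"].mean()
    assert means["Devonian"] > means["Jurassic"] > means["Rotliegend"]


def test_lab_zero_noise_limit_returns_truth(cohort):
    cfg = SimConfig(lab_bias=(0.0, 0.0, 0.0), lab_sd_low=1e-12, lab_sd_high=1e-12)
    table = generate_lab_measurements(cohort, cfg)
    for col in ("lab_1", "lab_2", "lab_3", "lab_avg"):
        assert np.allclose(table[col], cohort["soc_true"], atol=1e-9)


def test_lab_bias_recovered_by_monte_carlo():
    """Mean(series3 - series1) over a large cohort recovers the configured
    +0.64 g/kg offset within 2 standard errors."""
    strata = tuple(Stratum(s.name, 3334 if s.name == "Devonian" else 3333, s.soc_mean, s.soc_sd) for s in SimConfig().strata)
    cfg = SimConfig(n_samples=10_000, strata=strata, master_seed=9)
    frame = generate_cohort(cfg)
    table = generate_lab_measurements(frame, cfg)
    diff = table["lab_3"] - table["lab_1"]
    se = diff.std(ddof=1) / np.sqrt(len(diff))
    assert diff.mean() == pytest.approx(0.64, abs=2 * se)


def test_lab_error_sd_anchors_and_clamping(sim_config):
    sd = lab_error_sd(np.array([5.0, 10.0, 17.5, 25.0, 40.0]), sim_config)
    assert sd[1] == pytest.approx(0.21)
    assert sd[3] == pytest.approx(0.65)
    assert sd[0] == pytest.approx(0.21)  # constant below the low anchor
    assert sd[4] == pytest.approx(0.65)  # constant above the high anchor
    assert 0.21 < sd[2] < 0.65


def test_lab_replicate_sd_increases_with_soc():
    strata = tuple(Stratum(s.name, 3334 if s.name == "Devonian" else 3333, s.soc_mean, s.soc_sd) for s in SimConfig().strata)
    cfg = SimConfig(n_samples=10_000, strata=strata, master_seed=13)
    frame = generate_cohort(cfg)
    table = generate_lab_measurements(frame, cfg)
    per_sample_sd = table[["lab_1", "lab_2", "lab_3"]].std(axis=1, ddof=1)
    low = per_sample_sd[frame["soc_true"] < 10].mean()
    high = per_sample_sd[frame["soc_true"] > 25].mean()
    assert high > low


def test_zero_noise_series_are_bit_identical(cohort):
    cfg = SimConfig(vnir_noise=quiet_noise(), mir_noise=quiet_noise())
    out = generate_spectral_series(cohort, None, cfg)
    for domain in (VNIR, MIR):
        s1, s2, s3 = (s.values for s in out.series[domain])
        assert np.array_equal(s1, s2) and np.array_equal(s2, s3)


def test_series_pair_correlation_above_099(spectral_series):
    for domain in (VNIR, MIR):
        a, b = spectral_series.series[domain][0], spectral_series.series[domain][1]
        for i in range(a.n_samples):
            assert np.corrcoef(a.values[i], b.values[i])[0, 1] > 0.99


def test_equal_soc_different_strata_have_distinct_mir_spectra():
    """Two samples with identical SOC but different mineralogy must differ
    in the clay (3600-3700 cm^-1) and quartz (1070-1280 cm^-1) bands."""
    frame = pd.DataFrame(
        {
            "sample_id": ["A", "B"],
            "stratum": ["Devonian", "Jurassic"],
            "soc_true": [15.0, 15.0],
            "frac_organic": [0.03, 0.03],
            "frac_clay": [0.55 * 0.97, 0.15 * 0.97],
            "frac_quartz": [0.45 * 0.97, 0.85 * 0.97],
            "organic_absorptivity": [1.0, 1.0],
        }
    )
    cfg = SimConfig(
        n_samples=2,
        strata=(Stratum("Devonian", 1, 26.2, 4.5), Stratum("Jurassic", 1, 14.7, 3.5)),
        vnir_noise=quiet_noise(),
        mir_noise=quiet_noise(),
    )
    out = generate_spectral_series(frame, None, cfg)
    mir = out.series[MIR][0]
    wn = mir.grid.values
    clay = (wn >= 3600) & (wn <= 3700)
    quartz = (wn >= 1070) & (wn <= 1280)
    organic = (wn >= 2870) & (wn <= 2950)
    diff = np.abs(mir.values[0] - mir.values[1])
    assert diff[clay].max() > 1e-3
    assert diff[quartz].max() > 1e-3
    # the carbon feature itself is shared: much smaller difference there
    assert diff[organic].max() < 0.2 * max(diff[clay].max(), diff[quartz].max())


def test_generation_is_reproducible(sim_config, cohort, lab_table, spectral_series):
    again = generate_cohort(sim_config)
    pd.testing.assert_frame_equal(again, cohort)
    pd.testing.assert_frame_equal(generate_lab_measurements(again, sim_config), lab_table)
    out = generate_spectral_series(again, None, sim_config)
    for domain in (VNIR, MIR):
        for s_new, s_old in zip(out.series[domain], spectral_series.series[domain]):
            assert np.array_equal(s_new.values, s_old.values)


def test_config_validation_errors():
    with pytest.raises(ValueError, match="sum"):
        SimConfig(n_samples=10)
    with pytest.raises(ValueError, match="bias"):
        SimConfig(lab_bias=(0.0, 0.0))
    with pytest.raises(ValueError, match="anchors"):
        SimConfig(lab_sd_low=0.0)


def test_config_yaml_round_trip(tmp_path, sim_config):
    path = tmp_path / "config.yaml"
    sim_config.to_yaml(path)
    assert SimConfig.from_yaml(path) == sim_config
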