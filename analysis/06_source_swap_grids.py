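"""Source-swap experiments: which uncertainty source moves the RMSE?

Grid 1 (swap-spectra): every combination of calibration x validation
spectral series (series 1-3 and their average) with the laboratory-
average reference fixed.  Grid 2 (swap-reference): every combination of
calibration x validation laboratory reference series (labs 1-3 and
their average) with the averaged spectra fixed.  All cells of a grid
share one fold plan, so cell contrasts reflect the swapped source.
"""
import argparse
from pathlib import Path

import pandas as pd

from socspec import (
    CVConfig,
    average_sets,
    reflectance_to_absorbance,
    run_source_grid,
    stratified_folds,
    trim_and_resample,
)
from socspec.io import read_reference_csv, read_spectra_csv
from socspec.spectra import DEFAULT_KEEP, REFLECTANCE, WAVELENGTH_NM, WAVENUMBER_CM
from socspec.synthetic import MIR, VNIR

AXIS = {VNIR: WAVELENGTH_NM, MIR: WAVENUMBER_CM}


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--reps", type=int, default=20)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = pd.read_csv(args.data / "cohort.csv")
    labs = read_reference_csv(args.data / "reference_soc.csv").set_index("sample_id")
    refs = {c: labs[c] for c in ("lab_1", "lab_2", "lab_3", "lab_avg")}
    cv = CVConfig(n_repetitions=args.reps, master_seed=args.seed)
    plan = stratified_folds(cohort, cv)

    for domain in (VNIR, MIR):
        sets = {}
        for s in (1, 2, 3):
            raw = read_spectra_csv(args.data / f"{domain}_series{s}.csv", AXIS[domain], REFLECTANCE)
            sets[f"{domain.upper()}_{s}"] = trim_and_resample(
                reflectance_to_absorbance(raw), *DEFAULT_KEEP[domain]
            )
        sets[f"{domain.upper()}_AVG"] = average_sets(list(sets.values()))

        spec_grid = run_source_grid(
            cohort, sets, {"lab_avg": labs["lab_avg"]}, "swap-spectra", cv, plan=plan
        )
        out = spec_grid.formatted("rmse")
        out.to_csv(args.out / f"{domain}_swap_spectra_rmse.csv")
        print(f"\n{domain.upper()} RMSE (g/kg), calibration spectra (rows) x "
              "validation spectra (columns), lab_avg reference:")
        print(out.to_string())

        ref_grid = run_source_grid(
            cohort, {f"{domain.upper()}_AVG": sets[f"{domain.upper()}_AVG"]},
            refs, "swap-reference", cv, plan=plan,
        )
        out = ref_grid.formatted("rmse")
        out.to_csv(args.out / f"{domain}_swap_reference_rmse.csv")
        print(f"\n{domain.upper()} RMSE (g/kg), calibration reference (rows) x "
              "validation reference (columns), averaged spectra:")
        print(out.to_string())


if __name__ == "__main__":
    main()
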