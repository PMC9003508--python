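"""Generate the synthetic triplicate cohort and write it out as CSV.

Produces the sample frame (strata, latent SOC, composition), the
triplicate laboratory reference table, and the triplicate VNIR/MIR
reflectance series (replicate-averaged series plus the raw replicate
scans needed for within-series repeatability).
"""
import argparse
from pathlib import Path

from socspec import SimConfig, generate_cohort, generate_lab_measurements, generate_spectral_series
from socspec.io import write_reference_csv, write_spectra_csv
from socspec.synthetic import MIR, VNIR


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    ap.add_argument("--seed", type=int, default=SimConfig().master_seed)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    config = SimConfig(master_seed=args.seed)
    config.to_yaml(args.out / "config.yaml")
    cohort = generate_cohort(config)
    cohort.to_csv(args.out / "cohort.csv", index=False)
    labs = generate_lab_measurements(cohort, config)
    write_reference_csv(labs, args.out / "reference_soc.csv")
    series = generate_spectral_series(cohort, None, config)
    for domain in (VNIR, MIR):
        for s, spectra in enumerate(series.series[domain]):
            write_spectra_csv(spectra, args.out / f"{domain}_series{s + 1}.csv")
        for (d, s), reps in series.replicates.items():
            if d != domain:
                continue
            for r, rep in enumerate(reps):
                write_spectra_csv(rep, args.out / f"{domain}_series{s + 1}_rep{r + 1}.csv")
    print(f"cohort: {len(cohort)} samples, strata "
          f"{cohort.groupby('stratum').size().to_dict()}")
    print(f"lab means (g/kg): {labs[['lab_1', 'lab_2', 'lab_3', 'lab_avg']].mean().round(2).to_dict()}")
    print(f"reflectance values clipped: {series.n_clipped}")
    print(f"wrote data to {args.out}")


if __name__ == "__main__":
    main()
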