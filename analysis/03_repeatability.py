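"""Spectral repeatability (S_r) summary for the simulated series.

Computes S_r = 1/(1-r) within each series (between its two replicate
scans) and between every pair of replicate-averaged series, for both
domains, and writes the distribution summaries (Q1, mean, Q3, SD, CV%)
as one table per domain.
"""
import argparse
from itertools import combinations
from pathlib import Path

import pandas as pd

from socspec import reflectance_to_absorbance, series_repeatability, trim_and_resample
from socspec.io import read_spectra_csv
from socspec.spectra import DEFAULT_KEEP, REFLECTANCE, WAVELENGTH_NM, WAVENUMBER_CM
from socspec.synthetic import MIR, VNIR

AXIS = {VNIR: WAVELENGTH_NM, MIR: WAVENUMBER_CM}


def load(path, domain):
    raw = read_spectra_csv(path, AXIS[domain], REFLECTANCE)
    return trim_and_resample(reflectance_to_absorbance(raw), *DEFAULT_KEEP[domain])


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for domain in (VNIR, MIR):
        rows = []
        for s in (1, 2, 3):  # within-series: the two replicate scans
            reps = [load(args.data / f"{domain}_series{s}_rep{r}.csv", domain) for r in (1, 2)]
            rows.append(series_repeatability(reps[0], reps[1], f"S_r({s})").to_row())
        sets = {s: load(args.data / f"{domain}_series{s}.csv", domain) for s in (1, 2, 3)}
        for a, b in combinations((1, 2, 3), 2):
            rows.append(series_repeatability(sets[a], sets[b], f"S_r({a},{b})").to_row())
        table = pd.DataFrame(rows).round(1)
        table.to_csv(args.out / f"{domain}_repeatability.csv", index=False)
        print(f"\n{domain.upper()} repeatability:")
        print(table.to_string(index=False))


if __name__ == "__main__":
    main()
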