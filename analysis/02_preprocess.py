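"""Preprocess the simulated spectra and check stratum separation by PCA.

Converts every series to absorbance, trims the low-SNR edges, resamples
to the working grids (2100 points VNIR, 1600 points MIR), averages the
three series per domain, and reports how well the first two principal
components separate the geological strata in each domain.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from socspec import average_sets, pca_scores, reflectance_to_absorbance, trim_and_resample
from socspec.io import read_spectra_csv, write_spectra_csv
from socspec.spectra import DEFAULT_KEEP, REFLECTANCE, WAVELENGTH_NM, WAVENUMBER_CM
from socspec.synthetic import MIR, VNIR

AXIS = {VNIR: WAVELENGTH_NM, MIR: WAVENUMBER_CM}


def stratum_separation(scores, strata):
    """Between-stratum vs within-stratum spread in the score plane."""
    centers = {}
    within = []
    for name in np.unique(strata):
        pts = scores[strata == name]
        centers[name] = pts.mean(axis=0)
        within.append(np.linalg.norm(pts - centers[name], axis=1).mean())
    cvals = np.array(list(centers.values()))
    between = np.mean(
        [np.linalg.norm(a - b) for i, a in enumerate(cvals) for b in cvals[i + 1:]]
    )
    return between / np.mean(within)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(args.data / "cohort.csv")
    strata = cohort["stratum"].to_numpy()

    for domain in (VNIR, MIR):
        sets = []
        for s in (1, 2, 3):
            raw = read_spectra_csv(
                args.data / f"{domain}_series{s}.csv", AXIS[domain], REFLECTANCE,
                series_label=f"{domain.upper()}_{s}",
            )
            sets.append(trim_and_resample(reflectance_to_absorbance(raw), *DEFAULT_KEEP[domain]))
        avg = average_sets(sets)
        write_spectra_csv(avg, args.out / f"{domain}_avg_absorbance.csv")
        print(f"{domain}: working grid {avg.grid.n_points} points")
        res = pca_scores(avg, 2)
        pd.DataFrame(
            {"sample_id": avg.sample_ids, "PC1": res.scores[:, 0], "PC2": res.scores[:, 1],
             "stratum": strata}
        ).to_csv(args.out / f"{domain}_pca_scores.csv", index=False)
        sep = stratum_separation(res.scores, strata)
        print(
            f"{domain}: PC1+PC2 explain {100 * res.explained_variance_ratio.sum():.1f}% "
            f"of variance; stratum separation ratio {sep:.2f}"
        )


if __name__ == "__main__":
    main()
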