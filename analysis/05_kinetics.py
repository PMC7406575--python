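#!/usr/bin/env python
"""Michaelis-Menten parameter recovery via the Hanes-Woolf linearization.

Generates noisy 8-point (0.25-10 g/L) rate data on a sugar-beet-like
substrate from known parameters (Km 21 mM GalA bonds, kcat 96 1/s) and fits
each replicate experiment; reports the noiseless fit and the Monte-Carlo
median.  Writes results/kinetics_recovery.csv.
"""

from pathlib import Path

import pandas as pd

from pectolyze.workflows import kinetics_recovery

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    result = kinetics_recovery(seed=SEED, km_mm=21.0, kcat_s=96.0, noise_cv=0.05, n_seeds=100)
    pd.DataFrame([result]).to_csv(OUT / "kinetics_recovery.csv", index=False)
    print(f"noiseless fit:  Km = {result['km_noiseless']:.2f} mM")
    print(f"5% noise, {result['n_fits']} replicates: median Km = {result['km_median']:.2f} mM, "
          f"median kcat = {result['kcat_median']:.1f} 1/s")


if __name__ == "__main__":
    main()
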