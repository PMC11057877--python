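#!/usr/bin/env python
"""Estimate cone λmax from synthetic microspectrophotometry scans.

Generates noisy absorbance scans around each cone template (386, 497, 515,
535 nm), runs the long-limb regression + template inversion on each, bins
scans with similar λmax (<=10 nm) and refits the bin means — the same
workflow applied to real MSP records.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from anemonevision.pigments import bin_scans, estimate_lambda_max
from anemonevision.synth import gen_msp_scans

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for i, lmax in enumerate((386.0, 497.0, 515.0, 535.0)):
        scans = gen_msp_scans(lmax, n=20, noise_sd=0.05, seed=SEED + i)
        fits = [(s, estimate_lambda_max(s, "A1")) for s in scans]
        binned = bin_scans(fits)
        per_scan = np.array([f.lambda_max for _, f in fits])
        for b in binned:
            rows.append(
                {
                    "true_lambda_max": lmax,
                    "bin_lambda_max": round(b.lambda_max, 2),
                    "n_scans": len(fits),
                    "scan_mean": round(float(per_scan.mean()), 2),
                    "scan_sd": round(float(per_scan.std(ddof=1)), 2),
                }
            )
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "pigment_fits.csv", index=False)
    print(table.to_string(index=False))
    bias = (table.bin_lambda_max - table.true_lambda_max).abs().max()
    print(f"\nmax |bin estimate - truth| = {bias:.2f} nm across the four cone classes")


if __name__ == "__main__":
    main()
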