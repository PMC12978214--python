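#!/usr/bin/env python
"""Fraction-frozen curves, T50 and cumulative Vali spectra per sample.

Reads the simulated assays from 01, pools the technical replicates, reports
T50 of the undiluted sample, and writes the merged cumulative spectra
N_m(T) (with propagated counting errors) under results/spectra/.
"""

from pathlib import Path

import numpy as np

from icenuc import (
    AssayDesign,
    FreezingAssay,
    fraction_frozen,
    merge_dilution_series,
    pool_replicates,
    t50,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "spectra"
    out.mkdir(parents=True, exist_ok=True)
    design = AssayDesign(n_dilutions=5)
    grid = np.arange(-0.1, -30.0001, -0.1)
    for name in ("two_mode", "three_mode"):
        reps = [
            FreezingAssay.from_csv(ROOT / "assays" / f"{name}_rep{r}.csv", design)
            for r in (1, 2, 3)
        ]
        pooled = pool_replicates(reps)
        curve = fraction_frozen(pooled, grid)
        spectrum = merge_dilution_series(curve, pooled.design)
        spectrum.to_tsv(out / f"{name}_spectrum.tsv")
        t = t50(curve, dilution_index=0)
        pts = spectrum.points
        # the region below ~-23 degC is pure-water background freezing
        plateau = pts.loc[pts["T_C"] >= -20.0, "Nm_per_mg"].max()
        print(
            f"{name}: T50(undiluted) = {t:.1f} degC, "
            f"{len(pts)} spectrum points, N_m plateau ~ {plateau:.3g}/mg"
        )


if __name__ == "__main__":
    main()
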