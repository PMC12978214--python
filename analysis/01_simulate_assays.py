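#!/usr/bin/env python
"""Simulate droplet-freezing dilution series for two fungal-IN-like samples.

Generates synthetic TINA-style assays (96 droplets of 3 ul per 10-fold
dilution, 0 to -30 degC) from the Gaussian-subpopulation mixtures inferred
for the two study organisms: a two-mode sample (modes -5.9/-7.5 degC,
attributed to tetramers/trimers) and a three-mode sample (-5.6/-6.5/-7.5,
pentamers/tetramers/trimers).  Three technical replicates each, as in the
laboratory protocol.  Writes per-droplet CSVs under results/assays/.
"""

from pathlib import Path

import numpy as np

from icenuc import AssayDesign, SubpopulationMixture, sample_assay

OUT = Path(__file__).resolve().parents[1] / "results" / "assays"

SAMPLES = {
    # weights chosen equal per mode; N_tot sets lambda ~ 300 undiluted
    "two_mode": SubpopulationMixture(
        weights=[0.5, 0.5], modes=[-5.9, -7.5], spreads=[0.3, 0.3], n_tot=1e5
    ),
    "three_mode": SubpopulationMixture(
        weights=[1 / 3, 1 / 3, 1 / 3],
        modes=[-5.6, -6.5, -7.5],
        spreads=[0.3, 0.3, 0.3],
        n_tot=1e5,
    ),
}


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = AssayDesign(n_dilutions=5)
    ss = np.random.SeedSequence(seed)
    for (name, mixture), child in zip(SAMPLES.items(), ss.spawn(len(SAMPLES))):
        for rep, sub in enumerate(child.spawn(3), start=1):
            assay = sample_assay(
                mixture, design, seed=int(sub.generate_state(1)[0] % 2**31)
            )
            assay.sample_name = f"{name}_rep{rep}"
            path = OUT / f"{name}_rep{rep}.csv"
            assay.to_csv(path)
            n_frozen = assay.records["freeze_temp_C"].notna().sum()
            print(f"{path.name}: {n_frozen}/{len(assay.records)} droplets froze")


if __name__ == "__main__":
    main()
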