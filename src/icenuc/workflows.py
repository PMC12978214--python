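"""End-to-end pipelines with seeding, provenance manifests and file contracts.

Two workflows chain the library stages:

* spectrum pipeline: simulate (or load) a droplet-freezing dilution series,
  compute fraction-frozen curves and the merged Vali spectrum, then recover
  the Gaussian-subpopulation mixture;
* nucleation pipeline: optionally calibrate the interfacial-energy scale
  against an anchor aggregate, then tabulate T_het versus aggregate size.

Every stochastic stage draws a recorded sub-seed from the config seed, so a
config fully determines all outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .assay import AssayDesign, FreezingAssay, sample_assay
from .cnt import NucleationSurface, ThermoModel, aggregate_series, calibrate
from .errors import DataError
from .hub import differential, preprocess, select_components
from .mixture import SubpopulationMixture
from .spectra import fraction_frozen, merge_dilution_series


@dataclass
class RunConfig:
    """Serializable configuration of a pipeline run."""

    seed: int = 0
    design: dict = field(default_factory=dict)
    mixture: dict | None = None
    assay_csv: str | None = None
    fit: dict = field(default_factory=dict)
    thermo: dict = field(default_factory=dict)
    nucleation: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "design": self.design,
            "mixture": self.mixture,
            "assay_csv": self.assay_csv,
            "fit": self.fit,
            "thermo": self.thermo,
            "nucleation": self.nucleation,
            "log_level": self.log_level,
        }

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise DataError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def subseeds(self, n: int) -> list[int]:
        """Derived, recorded sub-seeds for the stochastic stages."""
        ss = np.random.SeedSequence(self.seed)
        return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(outdir: Path, config: RunConfig, seeds: list[int], files: list[str]) -> None:
    manifest = {
        "icenuc_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "subseeds": seeds,
        "outputs": sorted(files),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_spectrum_pipeline(config: RunConfig, outdir) -> dict:
    """Assay -> fraction frozen -> Vali spectrum -> mixture decomposition.

    Writes ``assay.csv``, ``spectrum.tsv``, ``mixture.json``, ``nm.tsv`` and
    a provenance ``manifest.json``; returns the artifact paths plus the
    fitted mixture.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = AssayDesign(**config.design)
    sim_seed, fit_seed = config.subseeds(2)
    if config.assay_csv is not None:
        path = Path(config.assay_csv)
        if not path.exists():
            raise DataError(f"assay CSV not found: {path}")
        assay = FreezingAssay.from_csv(path, design)
    elif config.mixture is not None:
        truth = SubpopulationMixture.from_dict(config.mixture)
        assay = sample_assay(truth, design, seed=sim_seed)
    else:
        raise DataError("config must provide either assay_csv or mixture")
    assay.to_csv(outdir / "assay.csv")

    grid = np.arange(
        design.T_start - design.T_resolution,
        design.T_stop - 1e-9,
        -design.T_resolution,
    )
    curve = fraction_frozen(assay, grid)
    spectrum = merge_dilution_series(curve, design)
    spectrum.to_tsv(outdir / "spectrum.tsv")

    fit = dict(config.fit)
    p_max = int(fit.pop("p_max", 3))
    T_min = fit.pop("T_min", -20.0)
    smoothed = preprocess(spectrum, T_min=T_min)
    model = select_components(smoothed, p_max=p_max, seed=fit_seed, **fit)
    with open(outdir / "mixture.json", "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)
    nm_grid = np.arange(smoothed.T_grid[0], smoothed.T_grid[-1] - 1e-9, -0.05)
    nm = differential(model, nm_grid)
    with open(outdir / "nm.tsv", "w") as fh:
        fh.write("T_C\tnm\n")
        for t, v in zip(nm_grid, nm):
            fh.write(f"{t:.3f}\t{v:.6g}\n")
    files = ["assay.csv", "spectrum.tsv", "mixture.json", "nm.tsv"]
    _write_manifest(outdir, config, [sim_seed, fit_seed], files)
    return {"mixture": model, "outdir": outdir, "files": files}


def run_nucleation_pipeline(config: RunConfig, outdir) -> dict:
    """Calibrate (optionally) and tabulate T_het versus aggregate size."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thermo = ThermoModel(**config.thermo)
    nuc = dict(config.nucleation)
    anchor = nuc.get("calibrate_anchor")  # {"n": 3, "length_nm": 19, "T_het_C": -7.5}
    if anchor:
        surface = NucleationSurface(
            monomer_length=float(anchor["length_nm"]) * 1e-9,
            n_monomers=int(anchor["n"]),
        )
        thermo = calibrate(surface, float(anchor["T_het_C"]), thermo)
    n_max = int(nuc.get("n_max", 8))
    lengths_nm = nuc.get("lengths_nm", [19.0, 25.3])
    files = []
    for L in lengths_nm:
        series = aggregate_series(L * 1e-9, n_max, thermo)
        name = f"aggregate_series_L{L:g}nm.tsv"
        series.to_csv(outdir / name, sep="\t", index=False)
        files.append(name)
    record = {
        "gamma_m": thermo.gamma_m,
        "provenance": thermo.provenance,
        "n_max": n_max,
        "lengths_nm": lengths_nm,
    }
    with open(outdir / "calibration.json", "w") as fh:
        json.dump(record, fh, indent=2)
    files.append("calibration.json")
    _write_manifest(outdir, config, [], files)
    return {"thermo": thermo, "outdir": outdir, "files": files}
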