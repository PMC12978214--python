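"""Synthetic droplet-freezing assays with TINA-style statistics.

Emulates a twin-plate ice nucleation assay: an IN sample is serially diluted
(10-fold by default), 96 droplets of 3 ul per dilution are cooled at a
constant rate from 0 to -30 degC, and each droplet's freezing temperature is
recorded with an instrument uncertainty of +-0.2 degC.  Droplets containing
no IN freeze at the pure-water background (~-23 degC and below).

The statistical model: the number of INs per droplet at dilution d is Poisson
with mean lambda_d = N_tot * C_m / step**d * V; each IN draws a characteristic
temperature from the sample's Gaussian-mixture distribution P_u(T); the
droplet freezes at the warmest of those temperatures (or at a background draw
if none is warmer).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .errors import DataError
from .mixture import SubpopulationMixture

#: sentinel for droplets still liquid at T_stop (stored as NaN / empty CSV cell)
UNFROZEN = float("nan")

MAX_LAMBDA = 1e9


@dataclass(frozen=True)
class AssayDesign:
    """Geometry and protocol of a droplet-freezing dilution series.

    Defaults follow the high-throughput twin-plate assay: 96 droplets of
    3 ul per 10-fold dilution, cooled from 0 to -30 degC with +-0.2 degC
    temperature uncertainty, pure-water background freezing below -23 degC.
    """

    droplet_volume_ul: float = 3.0
    droplets_per_dilution: int = 96
    dilution_step: float = 10.0
    n_dilutions: int = 5
    initial_mass_conc: float = 1.0  # mg/ml
    T_start: float = 0.0
    T_stop: float = -30.0
    T_resolution: float = 0.1
    temp_noise_sd: float = 0.2
    background_mu: float = -24.5
    background_sd: float = 1.0
    background_cap: float = -23.0
    background_enabled: bool = True

    def __post_init__(self) -> None:
        if self.droplet_volume_ul <= 0:
            raise ValueError("droplet_volume must be > 0")
        if self.T_stop >= self.T_start:
            raise ValueError("T_stop must be below T_start")
        if self.dilution_step <= 1:
            raise ValueError("dilution_step must be > 1")
        if self.background_cap > -23.0 or self.background_cap >= self.T_start:
            raise ValueError("background_cap must be <= -23 degC and below T_start")
        if self.n_dilutions < 1 or self.droplets_per_dilution < 1:
            raise ValueError("need at least one dilution and one droplet")
        if self.T_resolution <= 0 or self.temp_noise_sd < 0:
            raise ValueError("invalid temperature resolution/noise")

    @property
    def droplet_volume_ml(self) -> float:
        return self.droplet_volume_ul * 1e-3

    def mass_conc(self, dilution_index: int) -> float:
        """Sample mass concentration (mg/ml) at a given dilution."""
        return self.initial_mass_conc / self.dilution_step**dilution_index

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FreezingAssay:
    """Per-droplet freezing temperatures across a dilution series.

    ``records`` has columns ``dilution_index, droplet_id, freeze_temp_C``
    with NaN marking droplets that never froze above T_stop.
    """

    design: AssayDesign
    records: pd.DataFrame
    seed: int | None = None
    sample_name: str = "synthetic"

    def __post_init__(self) -> None:
        expected = self.design.droplets_per_dilution * self.design.n_dilutions
        if len(self.records) != expected:
            raise ValueError(
                f"record count {len(self.records)} != droplets x dilutions {expected}"
            )
        temps = self.records["freeze_temp_C"].to_numpy()
        frozen = temps[np.isfinite(temps)]
        if frozen.size and (
            frozen.min() < self.design.T_stop - 1e-9
            or frozen.max() > self.design.T_start + 1e-9
        ):
            raise ValueError("freeze temperatures outside [T_stop, T_start]")

    def to_csv(self, path_or_buf) -> None:
        df = self.records.copy()
        df.insert(0, "sample", self.sample_name)
        df.to_csv(path_or_buf, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path_or_buf, design: AssayDesign) -> "FreezingAssay":
        df = pd.read_csv(path_or_buf)
        required = {"dilution_index", "droplet_id", "freeze_temp_C"}
        if not required.issubset(df.columns):
            raise DataError(f"assay CSV must have columns {sorted(required)}")
        name = str(df["sample"].iloc[0]) if "sample" in df.columns else "unknown"
        records = df[["dilution_index", "droplet_id", "freeze_temp_C"]].astype(
            {"dilution_index": int, "droplet_id": int, "freeze_temp_C": float}
        )
        return cls(design=design, records=records, sample_name=name)


def _truncated_normal(
    rng: np.random.Generator, mu: float, sd: float, upper: float, size: int
) -> np.ndarray:
    """Gaussian(mu, sd) truncated above at ``upper`` via inverse-CDF sampling."""
    cap = ndtr((upper - mu) / sd)
    u = rng.random(size) * cap
    # clip away from 0 to keep ndtri finite
    return mu + sd * ndtri(np.clip(u, 1e-300, 1.0))


def sample_assay(
    mixture: SubpopulationMixture, design: AssayDesign, seed: int
) -> FreezingAssay:
    """Simulate one full dilution series of droplet freezing temperatures.

    For each droplet at dilution d the IN count is Poisson with mean
    lambda_d = N_tot * C_m(d) * V; the droplet freezes at the warmest
    characteristic temperature among its INs, or at a background draw
    (truncated Gaussian) when that is warmer or no IN is present.  Instrument
    noise is added after the max, the result quantized to T_resolution and
    censored to UNFROZEN below T_stop.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(design.n_dilutions):
        lam = mixture.n_tot * design.mass_conc(d) * design.droplet_volume_ml
        if not np.isfinite(lam) or lam > MAX_LAMBDA:
            raise DataError(f"mean IN count per droplet {lam:g} exceeds {MAX_LAMBDA:g}")
        n = design.droplets_per_dilution
        counts = rng.poisson(lam, size=n)
        warmest = np.full(n, -np.inf)
        for j, k in enumerate(counts):
            if k > 0:
                warmest[j] = mixture.sample(rng, int(k)).max()
        if design.background_enabled:
            background = _truncated_normal(
                rng,
                design.background_mu,
                design.background_sd,
                design.background_cap,
                n,
            )
        else:
            background = np.full(n, -np.inf)
        freeze = np.maximum(warmest, background)
        freeze = freeze + rng.normal(0.0, design.temp_noise_sd, size=n)
        freeze = np.round(freeze / design.T_resolution) * design.T_resolution
        freeze = np.minimum(freeze, design.T_start)
        freeze = np.where(freeze < design.T_stop, np.nan, freeze)
        # droplets with no IN and background disabled stay liquid
        freeze = np.where(np.isneginf(freeze), np.nan, freeze)
        for j in range(n):
            rows.append((d, j, freeze[j]))
    records = pd.DataFrame(
        rows, columns=["dilution_index", "droplet_id", "freeze_temp_C"]
    )
    return FreezingAssay(design=design, records=records, seed=seed)


def pool_replicates(assays: list[FreezingAssay]) -> FreezingAssay:
    """Pool technical replicates of the same design into one assay.

    Droplet ids are offset per replicate; all replicates must share the
    dilution structure.  Mirrors the protocol of running each freezing
    experiment at least three times and analyzing the combined spectrum.
    """
    if not assays:
        raise ValueError("no assays to pool")
    base = assays[0].design
    frames = []
    for k, a in enumerate(assays):
        if (
            a.design.n_dilutions != base.n_dilutions
            or a.design.dilution_step != base.dilution_step
            or a.design.initial_mass_conc != base.initial_mass_conc
            or a.design.droplet_volume_ul != base.droplet_volume_ul
        ):
            raise ValueError("replicate designs differ")
        r = a.records.copy()
        r["droplet_id"] += k * a.design.droplets_per_dilution
        frames.append(r)
    pooled_design = AssayDesign(
        **{
            **base.to_dict(),
            "droplets_per_dilution": sum(
                a.design.droplets_per_dilution for a in assays
            ),
        }
    )
    return FreezingAssay(
        design=pooled_design,
        records=pd.concat(frames, ignore_index=True),
        sample_name=assays[0].sample_name,
    )


def expected_fraction(
    mixture: SubpopulationMixture, lambda_per_droplet: float, T
) -> np.ndarray | float:
    """Analytic frozen fraction 1 - exp(-lambda * F_u(T)), background ignored.

    F_u(T) is the fraction of INs with characteristic temperature >= T; a
    droplet is frozen at T iff it holds at least one such IN (Poisson
    thinning), giving the Vali relation in expectation.
    """
    if lambda_per_droplet < 0:
        raise ValueError("lambda must be >= 0")
    F = mixture.survival(T)
    return 1.0 - np.exp(-lambda_per_droplet * F)
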