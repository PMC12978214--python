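"""Fraction-frozen curves, T50, and cumulative Vali spectra N_m(T).

Converts per-droplet freezing temperatures into the standard observables of
droplet-freezing assays: the fraction of frozen droplets f_ice(T) per
dilution, the half-freezing temperature T50, and the cumulative number of ice
nucleators per unit mass N_m(T) obtained from Vali's formula

    N_m(T) = -ln(1 - f_ice(T)) / (V_d * C_m)

with binomial counting error propagated to sigma_Nm.  A dilution series is
merged into a single spectrum by applying the formula per dilution with that
dilution's mass concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assay import AssayDesign, FreezingAssay
from .errors import DataError, EmptySpectrumError, ExcludedPointError, NoT50Error


@dataclass
class FractionFrozenCurve:
    """f_ice on a descending temperature grid, one row per dilution."""

    T_grid: np.ndarray  # degC, strictly descending
    f_ice: np.ndarray  # shape (n_dilutions, len(T_grid))
    n_droplets: np.ndarray  # per dilution

    def __post_init__(self) -> None:
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        self.f_ice = np.atleast_2d(np.asarray(self.f_ice, dtype=float))
        self.n_droplets = np.atleast_1d(np.asarray(self.n_droplets, dtype=int))
        if np.any(np.diff(self.T_grid) >= 0):
            raise ValueError("T_grid must be strictly descending")
        if np.any(self.f_ice < 0) or np.any(self.f_ice > 1):
            raise ValueError("f_ice outside [0, 1]")
        # cooling can only freeze more droplets
        if np.any(np.diff(self.f_ice, axis=1) < -1e-12):
            raise ValueError("f_ice must be nondecreasing as T decreases")


@dataclass
class CumulativeSpectrum:
    """Merged Vali spectrum: N_m(T) points with uncertainties.

    ``points`` columns: ``T_C, Nm_per_mg, sigma_Nm, dilution_index``, sorted
    by descending temperature.
    """

    points: pd.DataFrame
    droplet_volume_ml: float
    mass_conc: dict  # dilution_index -> mg/ml
    n_droplets: dict | None = None  # dilution_index -> droplet count

    def __post_init__(self) -> None:
        pts = self.points
        if np.any(pts["Nm_per_mg"].to_numpy() < 0):
            raise ValueError("N_m must be >= 0")
        if not np.all(np.isfinite(pts["sigma_Nm"].to_numpy())):
            raise ValueError("sigma_Nm must be finite (f = 1 points excluded)")

    def to_tsv(self, path_or_buf) -> None:
        self.points.to_csv(
            path_or_buf,
            sep="\t",
            index=False,
            columns=["T_C", "Nm_per_mg", "sigma_Nm", "dilution_index"],
        )

    @classmethod
    def from_tsv(
        cls, path_or_buf, droplet_volume_ml: float = 3e-3, mass_conc: dict | None = None
    ) -> "CumulativeSpectrum":
        pts = pd.read_csv(path_or_buf, sep="\t")
        required = {"T_C", "Nm_per_mg", "sigma_Nm", "dilution_index"}
        if not required.issubset(pts.columns):
            raise DataError(f"spectrum TSV must have columns {sorted(required)}")
        return cls(
            points=pts, droplet_volume_ml=droplet_volume_ml, mass_conc=mass_conc or {}
        )


def fraction_frozen(assay: FreezingAssay, T_grid) -> FractionFrozenCurve:
    """Count frozen droplets per dilution at each grid temperature.

    f_ice(T, d) = #(droplets of dilution d with freeze_temp >= T) / n_d;
    unfrozen droplets (NaN) never count.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.size == 0 or np.any(np.diff(T_grid) >= 0):
        raise ValueError("T_grid must be non-empty and strictly descending")
    design = assay.design
    if T_grid.max() > design.T_start + 1e-9 or T_grid.min() < design.T_stop - 1e-9:
        raise ValueError("T_grid outside the assay's cooling range")
    rows, counts = [], []
    for d, grp in assay.records.groupby("dilution_index", sort=True):
        temps = grp["freeze_temp_C"].to_numpy()
        temps = temps[np.isfinite(temps)]
        n = len(grp)
        if n == 0:
            raise DataError(f"dilution {d} has no droplets")
        rows.append((temps[:, None] >= T_grid[None, :] - 1e-12).sum(axis=0) / n)
        counts.append(n)
    return FractionFrozenCurve(
        T_grid=T_grid, f_ice=np.array(rows), n_droplets=np.array(counts)
    )


def t50(curve: FractionFrozenCurve, dilution_index: int = 0) -> float:
    """Temperature at which half the droplets of a dilution have frozen.

    Linear interpolation between the two grid temperatures bracketing
    f_ice = 0.5; exact grid hits are returned as-is.
    """
    f = curve.f_ice[dilution_index]
    T = curve.T_grid
    for i in range(len(T)):
        if f[i] >= 0.5:
            if f[i] == 0.5 or i == 0:
                return float(T[i])
            f0, f1 = f[i - 1], f[i]
            if f1 == f0:
                return float(T[i])
            frac = (0.5 - f0) / (f1 - f0)
            return float(T[i - 1] + frac * (T[i] - T[i - 1]))
    raise NoT50Error(f"dilution {dilution_index}: f_ice never reaches 0.5")


def vali_nm(f: float, V_d: float, C_m: float, n: int) -> tuple[float, float]:
    """Vali's formula with Gaussian-propagated binomial counting error.

    N_m = -ln(1 - f) / (V_d * C_m)  [INs per mg], with
    sigma_f = sqrt(f (1 - f) / n) and sigma_Nm = sigma_f / ((1 - f) V_d C_m).

    V_d in ml, C_m in mg/ml, n = droplet count behind the frequency f.
    """
    if V_d <= 0 or C_m <= 0:
        raise ValueError("V_d and C_m must be > 0")
    if n < 1:
        raise ValueError("need at least one droplet")
    if f < -1e-12 or f > 1 + 1e-12:
        raise ValueError(f"invalid frozen fraction {f}")
    f = min(max(f, 0.0), 1.0)
    if f == 1.0:
        raise ExcludedPointError("f_ice = 1: Vali estimate diverges")
    if f == 0.0:
        return 0.0, 0.0
    denom = V_d * C_m
    nm = -np.log1p(-f) / denom
    sigma_f = np.sqrt(f * (1.0 - f) / n)
    sigma_nm = sigma_f / ((1.0 - f) * denom)
    return float(nm), float(sigma_nm)


def merge_dilution_series(
    curve: FractionFrozenCurve, design: AssayDesign
) -> CumulativeSpectrum:
    """Merge a dilution series into one cumulative spectrum.

    Applies ``vali_nm`` per dilution with that dilution's mass concentration;
    censors f = 0 (no information) and f = 1 (log divergence); keeps
    overlapping-temperature points from different dilutions as separate rows.
    """
    V = design.droplet_volume_ml
    rows = []
    for d in range(curve.f_ice.shape[0]):
        C_m = design.mass_conc(d)
        n = int(curve.n_droplets[d])
        for T, f in zip(curve.T_grid, curve.f_ice[d]):
            if f <= 0.0 or f >= 1.0:
                continue
            nm, s = vali_nm(float(f), V, C_m, n)
            rows.append((float(T), nm, s, d))
    if not rows:
        raise EmptySpectrumError("all points censored (f = 0 or f = 1 everywhere)")
    pts = pd.DataFrame(rows, columns=["T_C", "Nm_per_mg", "sigma_Nm", "dilution_index"])
    pts = pts.sort_values(
        ["T_C", "dilution_index"], ascending=[False, True], ignore_index=True
    )
    return CumulativeSpectrum(
        points=pts,
        droplet_volume_ml=V,
        mass_conc={d: design.mass_conc(d) for d in range(curve.f_ice.shape[0])},
        n_droplets={d: int(curve.n_droplets[d]) for d in range(curve.f_ice.shape[0])},
    )
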