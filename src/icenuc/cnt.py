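"""Classical-nucleation-theory prediction of heterogeneous freezing on
finite ice-binding surfaces.

An ice-nucleating protein aggregate is modelled as a flat rectangular
ice-binding patch of width W_n = n x 3.4 nm and length L that binds ice as
strongly as ice binds itself (binding free energy Dgamma_bind = -2
gamma_ice-liquid, i.e. complete wetting), with a three-phase line tension tau
at the ice-protein-water contact line.  Two stages of the minimum free-energy
path produce two barriers:

* stage A, film spreading: a thin circular ice film (one bilayer, thickness
  d0) spreads over the patch against the line tension;
* stage B, growth into bulk: with the patch covered, the contact line pins at
  the patch perimeter and the nucleus bulges out as a circular-segment ridge
  (chord W_n, bulge angle phi) of length L closed by two half spherical caps,
  measured relative to the flat covered state.

The larger barrier limits nucleation.  Scanning temperature on a 0.1 degC
grid from the melting point down to the homogeneous-nucleation regime
(-46 degC), the heterogeneous freezing temperature T_het is the warmest
temperature at which the nucleation rate J = A0 exp(-DG*/kT) reaches the
threshold (100 per second, matching crystallization at 1 degC/min cooling).

The single uncertain scale, the ice-liquid interfacial free energy gamma_m at
melting, is calibratable against one observed freezing mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import CalibrationError

T_MELT = 273.15  # K
SCAN_FLOOR_C = -46.0  # homogeneous nucleation takes over below this
SCAN_STEP_C = 0.1
MONOMER_WIDTH_M = 3.4e-9


@dataclass(frozen=True)
class ThermoModel:
    """Thermodynamic and kinetic parameters of supercooled water.

    Volumetric enthalpy of fusion and heat-capacity difference parameterize
    the chemical-potential driving force; gamma_m (ice-liquid interfacial
    free energy at melting, J/m^2) is the single calibratable scale with a
    linear temperature slope dgamma_dT.  The binding free energy of the
    patch is fixed at Dgamma_bind = -2 gamma_sl(T) (perfect ice binder).
    """

    T_m: float = T_MELT
    delta_h_fv: float = 3.06e8  # J/m^3 at T_m
    delta_cp_v: float = 2.0e6  # J/(m^3 K)
    gamma_m: float = 3.08e-2  # J/m^2, calibratable
    dgamma_dT: float = 1.8e-4  # J/(m^2 K)
    tau: float = 1.0e-11  # N (10 pN line tension)
    prefactor_A0: float = 1e26  # 1/s per surface
    J_threshold: float = 1e2  # 1/s
    film_thickness_d0: float = 3.7e-10  # m (one ice bilayer)
    k_B: float = 1.380649e-23  # J/K
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "T_m",
            "delta_h_fv",
            "delta_cp_v",
            "gamma_m",
            "dgamma_dT",
            "tau",
            "prefactor_A0",
            "J_threshold",
            "film_thickness_d0",
            "k_B",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def dgamma_bind(self, T_K: float) -> float:
        """Binding free energy per area of the patch to ice (negative)."""
        return -2.0 * gamma_sl(T_K, self)


@dataclass(frozen=True)
class NucleationSurface:
    """Rectangular ice-binding patch of n side-by-side monomers."""

    monomer_length: float  # m
    n_monomers: int = 1
    monomer_width: float = MONOMER_WIDTH_M  # m

    def __post_init__(self) -> None:
        if self.n_monomers < 1:
            raise ValueError("n_monomers must be >= 1")
        if self.monomer_length <= 0 or self.monomer_width <= 0:
            raise ValueError("surface dimensions must be > 0")

    @property
    def width(self) -> float:
        """Aggregate width W_n = n x monomer width (m)."""
        return self.n_monomers * self.monomer_width

    @property
    def length(self) -> float:
        return self.monomer_length


@dataclass
class BarrierProfile:
    """Stage barriers, limiting barrier and nucleation rate at one T."""

    T_C: float
    barrier_on_surface: float  # J, film-spreading stage
    barrier_into_bulk: float  # J, bulge stage
    limiting_barrier: float  # J
    rate: float  # 1/s


def delta_mu_v(T: float, thermo: ThermoModel) -> float:
    """Volumetric chemical-potential driving force |Dmu_v|(T) in J/m^3.

    |Dmu_v| = dh_fv DT/T_m - dcp_v (DT - T ln(T_m/T)), DT = T_m - T; zero at
    coexistence and monotone increasing with supercooling on the valid range.
    """
    T = float(T)
    if T > thermo.T_m:
        raise ValueError("T above the melting point")
    if T <= 150.0:
        raise ValueError("T outside the parameterization range")
    dT = thermo.T_m - T
    return thermo.delta_h_fv * dT / thermo.T_m - thermo.delta_cp_v * (
        dT - T * np.log(thermo.T_m / T)
    )


def gamma_sl(T: float, thermo: ThermoModel) -> float:
    """Ice-liquid interfacial free energy, linear in T around melting."""
    g = thermo.gamma_m + thermo.dgamma_dT * (float(T) - thermo.T_m)
    if np.any(np.asarray(g) <= 0):
        raise ValueError("gamma_sl became non-positive at this temperature")
    return g


def film_barrier(surface: NucleationSurface, T: float, thermo: ThermoModel) -> float:
    """Stage-A barrier: ice film of thickness d0 spreading over the patch.

    DG_A(a) = -(|Dmu| d0 + gamma_sl) pi a^2 + (gamma_sl d0 + tau) 2 pi a
    (the perfectly binding patch makes spreading favorable; growth is
    opposed by the line tension and the film rim).  Returns the maximum
    along a, capped where the film reaches the patch boundary.
    """
    g = gamma_sl(T, thermo)
    mu = delta_mu_v(T, thermo)
    d0 = thermo.film_thickness_d0
    gain = mu * d0 + g  # per unit film area
    cost = g * d0 + thermo.tau  # per unit rim length
    a_star = cost / gain
    a = min(a_star, min(surface.width, surface.length) / 2.0)
    dg = -gain * np.pi * a**2 + cost * 2.0 * np.pi * a
    return max(float(dg), 0.0)


def _bulge_profile(
    W: float, L: float, mu: float, g: float, n_phi: int
) -> np.ndarray:
    """Free energy along the pinned-bulge path, sampled on a phi grid.

    Circular-segment ridge of chord W and bulge angle phi, radius
    r = W / (2 sin phi), length L, closed by two half spherical caps of the
    same r and phi.  Measured relative to the flat covered state, whose
    ice-liquid area is the flattened-nucleus footprint L W + pi W^2/4.
    """
    phi = np.linspace(np.pi / n_phi, np.pi * (1 - 1.0 / n_phi), n_phi)
    r = W / (2.0 * np.sin(phi))
    cos, sin = np.cos(phi), np.sin(phi)
    V = r**2 * (phi - sin * cos) * L + (np.pi / 3.0) * r**3 * (1 - cos) ** 2 * (
        2 + cos
    )
    A_lv = 2.0 * r * phi * L + 2.0 * np.pi * r**2 * (1 - cos)
    A_ref = L * W + np.pi * W**2 / 4.0
    return -mu * V + g * (A_lv - A_ref)


def bulge_barrier(
    surface: NucleationSurface,
    T: float,
    thermo: ThermoModel,
    n_phi: int = 2000,
) -> float:
    """Stage-B barrier: growth from the covered patch into bulk water.

    Maximum of the pinned-bulge free-energy path over a phi grid of
    ``n_phi`` points, clamped at 0 when the path is everywhere downhill.
    """
    g = gamma_sl(T, thermo)
    mu = delta_mu_v(T, thermo)
    dG = _bulge_profile(surface.width, surface.length, mu, g, n_phi)
    if not np.all(np.isfinite(dG)):
        raise ValueError("non-finite bulge geometry")
    return max(float(dG.max()), 0.0)


def barrier_profile(
    surface: NucleationSurface, T_C: float, thermo: ThermoModel, n_phi: int = 2000
) -> BarrierProfile:
    """Both stage barriers, the limiting barrier and the rate at one T."""
    T_K = thermo.T_m + T_C
    a = film_barrier(surface, T_K, thermo)
    b = bulge_barrier(surface, T_K, thermo, n_phi=n_phi)
    lim = max(a, b)
    rate = thermo.prefactor_A0 * np.exp(-lim / (thermo.k_B * T_K))
    return BarrierProfile(
        T_C=T_C,
        barrier_on_surface=a,
        barrier_into_bulk=b,
        limiting_barrier=lim,
        rate=float(rate),
    )


def _scan_grid(step: float = SCAN_STEP_C) -> np.ndarray:
    n = int(round(-SCAN_FLOOR_C / step))
    return -step * np.arange(1, n + 1)


def _log_rate_curve(
    surface: NucleationSurface,
    thermo: ThermoModel,
    grid_C: np.ndarray,
    n_phi: int = 2000,
) -> np.ndarray:
    """ln J(T) along the temperature scan (vectorized over T and phi)."""
    T_K = thermo.T_m + grid_C
    g = thermo.gamma_m + thermo.dgamma_dT * (T_K - thermo.T_m)
    dT = thermo.T_m - T_K
    mu = thermo.delta_h_fv * dT / thermo.T_m - thermo.delta_cp_v * (
        dT - T_K * np.log(thermo.T_m / T_K)
    )
    W, L = surface.width, surface.length
    phi = np.linspace(np.pi / n_phi, np.pi * (1 - 1.0 / n_phi), n_phi)
    r = W / (2.0 * np.sin(phi))
    cos, sin = np.cos(phi), np.sin(phi)
    V = r**2 * (phi - sin * cos) * L + (np.pi / 3.0) * r**3 * (1 - cos) ** 2 * (
        2 + cos
    )
    A_lv = 2.0 * r * phi * L + 2.0 * np.pi * r**2 * (1 - cos)
    A_ref = L * W + np.pi * W**2 / 4.0
    bulge = np.maximum(
        (-mu[:, None] * V[None, :] + g[:, None] * (A_lv - A_ref)[None, :]).max(axis=1),
        0.0,
    )
    d0 = thermo.film_thickness_d0
    gain = mu * d0 + g
    cost = g * d0 + thermo.tau
    a = np.minimum(cost / gain, min(W, L) / 2.0)
    film = np.maximum(-gain * np.pi * a**2 + cost * 2.0 * np.pi * a, 0.0)
    limiting = np.maximum(bulge, film)
    return np.log(thermo.prefactor_A0) - limiting / (thermo.k_B * T_K)


def t_het(
    surface: NucleationSurface,
    thermo: ThermoModel,
    step: float = SCAN_STEP_C,
    n_phi: int = 2000,
) -> float | None:
    """Heterogeneous freezing temperature (degC) of a surface.

    Warmest grid temperature (0.1 degC steps from 0 degC down to -46 degC)
    at which the nucleation rate reaches the threshold; None if the
    threshold is never reached above the homogeneous regime.
    """
    grid = _scan_grid(step)
    log_j = _log_rate_curve(surface, thermo, grid, n_phi=n_phi)
    hits = np.nonzero(log_j >= np.log(thermo.J_threshold))[0]
    if hits.size == 0:
        return None
    return float(round(grid[hits[0]], 10))


def _t_het_continuous(
    surface: NucleationSurface, thermo: ThermoModel, n_phi: int = 2000
) -> float | None:
    """Off-grid threshold crossing of ln J(T), for calibration only."""
    grid = _scan_grid()
    log_j = _log_rate_curve(surface, thermo, grid, n_phi=n_phi)
    target = np.log(thermo.J_threshold)
    hits = np.nonzero(log_j >= target)[0]
    if hits.size == 0:
        return None
    i = hits[0]
    if i == 0:
        return float(grid[0])
    t0, t1 = grid[i - 1], grid[i]
    l0, l1 = log_j[i - 1], log_j[i]
    return float(t0 + (target - l0) * (t1 - t0) / (l1 - l0))


def aggregate_series(
    monomer_length: float,
    n_max: int,
    thermo: ThermoModel,
    monomer_width: float = MONOMER_WIDTH_M,
) -> pd.DataFrame:
    """T_het versus aggregate size for side-by-side monomers.

    Tidy table with one row per n = 1..n_max: aggregate width W_n, T_het,
    and the two stage barriers evaluated at T_het.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    rows = []
    for n in range(1, n_max + 1):
        surf = NucleationSurface(
            monomer_length=monomer_length, n_monomers=n, monomer_width=monomer_width
        )
        t = t_het(surf, thermo)
        if t is None:
            rows.append((n, surf.width, np.nan, np.nan, np.nan))
        else:
            prof = barrier_profile(surf, t, thermo)
            rows.append(
                (n, surf.width, t, prof.barrier_on_surface, prof.barrier_into_bulk)
            )
    return pd.DataFrame(
        rows, columns=["n", "W_n_m", "T_het_C", "dG_A_J", "dG_B_J"]
    )


def calibrate(
    anchor_surface: NucleationSurface,
    anchor_T_het: float,
    thermo: ThermoModel,
    bracket: tuple[float, float] = (0.015, 0.045),
) -> ThermoModel:
    """Solve for gamma_m so the anchor surface freezes at the anchor mode.

    One-dimensional root-find (all other parameters fixed): the returned
    model reproduces ``anchor_T_het`` within 0.05 degC.  Warmer anchors
    require smaller gamma_m.
    """
    if anchor_T_het >= 0:
        raise ValueError("anchor_T_het must be below 0 degC")
    current = t_het(anchor_surface, thermo)
    if current is not None and abs(current - anchor_T_het) <= 0.05:
        # already on the anchor's plateau: calibration is a no-op
        return replace(
            thermo,
            provenance={
                **thermo.provenance,
                "calibration": {
                    "anchor_n_monomers": anchor_surface.n_monomers,
                    "anchor_length_m": anchor_surface.length,
                    "anchor_T_het_C": anchor_T_het,
                    "gamma_m": thermo.gamma_m,
                    "residual_C": float(current - anchor_T_het),
                    "no_op": True,
                },
            },
        )

    # aim the continuous threshold crossing a hair warmer than the anchor so
    # the grid-quantized t_het lands exactly on the anchor's grid point
    target = anchor_T_het + 1e-4

    def residual(gm: float) -> float:
        t = _t_het_continuous(anchor_surface, replace(thermo, gamma_m=gm))
        if t is None:
            # colder than the scan floor: report a large negative residual
            return SCAN_FLOOR_C - target
        return t - target

    lo, hi = bracket
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0:
        raise CalibrationError(
            f"no gamma_m in [{lo}, {hi}] J/m^2 reaches {anchor_T_het} degC "
            f"(residuals {r_lo:+.2f} / {r_hi:+.2f} degC at the bracket ends)"
        )
    gm = brentq(residual, lo, hi, xtol=1e-8)
    calibrated = replace(
        thermo,
        gamma_m=float(gm),
        provenance={
            **thermo.provenance,
            "calibration": {
                "anchor_n_monomers": anchor_surface.n_monomers,
                "anchor_length_m": anchor_surface.length,
                "anchor_T_het_C": anchor_T_het,
                "gamma_m": float(gm),
                "residual_C": float(residual(gm)),
            },
        },
    )
    achieved = t_het(anchor_surface, calibrated)
    if achieved is None or abs(achieved - anchor_T_het) > 0.05 + 1e-6:
        raise CalibrationError(
            f"calibrated model reproduces {achieved} instead of {anchor_T_het}"
        )
    return calibrated
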