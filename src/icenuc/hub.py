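"""Gaussian-subpopulation decomposition of cumulative freezing spectra.

Recovers the underlying distribution of heterogeneous ice-nucleation
temperatures P_u(T) behind a cumulative spectrum N_m(T) as a linear
combination of p normalized Gaussians:

    N_m(T) = N_tot * sum_i c_i * Phi((T_mode,i - T) / s_i)

The spectrum is spline-interpolated onto a uniform grid in log10 N_m,
smoothed with a short Savitzky-Golay filter, and the mixture parameters are
found by seeded stochastic global optimization (differential evolution)
minimizing the mean squared error on the log10 scale.  The number of
subpopulations is chosen as the lowest-MSE model over p = 1..p_max after
pruning negligible weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import differential_evolution
from scipy.signal import savgol_filter
from scipy.special import ndtr

from .errors import DataError
from .mixture import SubpopulationMixture
from .spectra import CumulativeSpectrum

DEFAULT_MODE_BOUNDS = (-25.0, -2.0)
DEFAULT_SPREAD_BOUNDS = (0.05, 5.0)
WEIGHT_FLOOR = 0.01


@dataclass
class SmoothedSpectrum:
    """log10 N_m on a uniform descending temperature grid."""

    T_grid: np.ndarray
    log10_Nm: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        self.log10_Nm = np.asarray(self.log10_Nm, dtype=float)
        if self.T_grid.size < 2 or self.T_grid[0] <= self.T_grid[-1]:
            raise ValueError("T_grid must be descending with >= 2 points")
        if not np.all(np.isfinite(self.log10_Nm)):
            raise ValueError("non-finite smoothed spectrum")


def preprocess(
    spectrum: CumulativeSpectrum,
    grid_step: float = 0.1,
    window_length: int = 3,
    polyorder: int = 1,
    T_min: float | None = None,
    T_max: float | None = None,
    f_window: tuple[float, float] | str | None = "auto",
    dedup: str = "weighted_mean",
    min_edge_count: float = 5.0,
) -> SmoothedSpectrum:
    """Interpolate log10 N_m onto a uniform grid and Savitzky-Golay smooth it.

    The filter window is in grid samples; the order-1 default reproduces
    straight lines exactly.  ``T_min``/``T_max`` optionally restrict the
    analysis window (e.g. to keep clear of the pure-water background);
    ``f_window`` keeps only points whose implied frozen fraction lies in the
    stated band — censoring-edge points (a single frozen or a single liquid
    droplet) carry large conditional biases in the Vali estimate and no
    stable information.  The default ``"auto"`` band requires at least
    ``min_edge_count`` expected droplets on each side (never narrower than
    3% of the droplets), so it adapts to pooled replicates.

    Overlapping dilutions at the same temperature are collapsed per the
    ``dedup`` policy: ``"weighted_mean"`` (default) inverse-variance
    averages log10 N_m across dilutions; ``"most_dilute"`` keeps the point
    from the highest dilution, whose Vali estimate is least distorted by
    the nonlinear interaction of droplet IN load with the instrument's
    temperature uncertainty.
    """
    pts = spectrum.points
    T = pts["T_C"].to_numpy(dtype=float)
    nm = pts["Nm_per_mg"].to_numpy(dtype=float)
    sig = pts["sigma_Nm"].to_numpy(dtype=float)
    dil = pts["dilution_index"].to_numpy()
    keep = nm > 0
    if f_window is not None and spectrum.mass_conc:
        conc = pts["dilution_index"].map(spectrum.mass_conc).to_numpy(dtype=float)
        f = 1.0 - np.exp(-nm * spectrum.droplet_volume_ml * conc)
        if f_window == "auto":
            if spectrum.n_droplets:
                n_d = pts["dilution_index"].map(spectrum.n_droplets).to_numpy(float)
            else:
                n_d = np.full(len(pts), 96.0)
            lo = np.maximum(0.03, min_edge_count / n_d)
            keep &= (f >= lo) & (f <= 1.0 - lo)
        else:
            keep &= (f >= f_window[0]) & (f <= f_window[1])
    if T_min is not None:
        keep &= T >= T_min
    if T_max is not None:
        keep &= T <= T_max
    T, nm, sig, dil = T[keep], nm[keep], sig[keep], dil[keep]
    if T.size < 4:
        raise DataError("need >= 4 spectrum points to preprocess")
    log_nm = np.log10(nm)
    uniq, inv = np.unique(T, return_inverse=True)
    if dedup == "most_dilute":
        order = np.lexsort((dil, inv))  # by T then dilution
        mean_log = np.empty(uniq.size)
        # last entry per temperature = highest dilution index
        mean_log[inv[order]] = log_nm[order]
    elif dedup == "weighted_mean":
        ratio = np.divide(nm, sig, out=np.ones_like(nm), where=sig > 0)
        w = np.where(sig > 0, ratio**2, 1.0)
        mean_log = np.bincount(inv, weights=w * log_nm) / np.bincount(inv, weights=w)
    else:
        raise ValueError(f"unknown dedup policy {dedup!r}")
    if uniq.size < 4:
        raise DataError("need >= 4 distinct temperatures after dedup")
    spline = PchipInterpolator(uniq, mean_log)
    grid = np.arange(uniq[-1], uniq[0] - 1e-12, -grid_step)
    values = spline(grid)
    if window_length > 1:
        wl = min(window_length, grid.size if grid.size % 2 else grid.size - 1)
        if wl > polyorder:
            values = savgol_filter(values, wl, polyorder)
    if not np.all(np.isfinite(values)):
        raise DataError("non-finite values after smoothing")
    return SmoothedSpectrum(
        T_grid=grid,
        log10_Nm=values,
        provenance={
            "spline": "pchip",
            "knots": uniq.tolist(),
            "window_length": window_length,
            "polyorder": polyorder,
            "grid_step": grid_step,
        },
    )


def mixture_cumulative(m: SubpopulationMixture, T) -> np.ndarray | float:
    """Forward map from the mixture to the cumulative spectrum N_m(T)."""
    return m.n_tot * m.survival(T)


def _unpack(x: np.ndarray, p: int):
    """Split a DE parameter matrix into modes, spreads, simplex weights."""
    modes = x[0:p]
    spreads = 10.0 ** x[p : 2 * p]
    raw = x[2 * p : 3 * p]
    weights = raw / raw.sum(axis=0)
    return modes, spreads, weights


def _objective(T_grid: np.ndarray, data_log: np.ndarray, p: int):
    """Vectorized MSE on log10 N_m for differential evolution.

    Parameter vector: [modes (p), log10 spreads (p), raw weights (p)]; raw
    weights are normalized onto the simplex.  The overall scale N_tot enters
    log10 N_m as an additive offset, so its MSE-optimal value is the mean
    residual and is concentrated out in closed form.
    """

    def f(x):
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[:, None]
        modes, spreads, w = _unpack(x, p)
        z = (modes[:, :, None] - T_grid[None, None, :]) / spreads[:, :, None]
        F = np.einsum("ps,pst->st", w, ndtr(z))
        log_F = np.log10(np.clip(F, 1e-300, None))
        resid = data_log[None, :] - log_F
        resid -= resid.mean(axis=1, keepdims=True)  # optimal log10 N_tot
        mse = np.mean(resid**2, axis=1)
        return mse[0] if squeeze else mse

    return f


def _optimal_log10_ntot(
    T_grid: np.ndarray, data_log: np.ndarray, modes, spreads, weights
) -> float:
    z = (np.asarray(modes)[:, None] - T_grid[None, :]) / np.asarray(spreads)[:, None]
    log_F = np.log10(np.clip(np.asarray(weights) @ ndtr(z), 1e-300, None))
    return float(np.mean(data_log - log_F))


def fit_mixture(
    s: SmoothedSpectrum,
    p: int,
    seed: int,
    bounds: dict | None = None,
    restarts: int = 5,
    maxiter: int = 300,
    popsize: int = 20,
) -> SubpopulationMixture:
    """Fit a p-component Gaussian mixture to a smoothed spectrum.

    Seeded differential-evolution global search (best of ``restarts``
    independent runs) over {c_i, T_mode,i, s_i}, minimizing the MSE between
    log10 of the model cumulative spectrum and the smoothed data; the scale
    N_tot is concentrated out in closed form on the log scale.  Mode bounds
    default to the data's temperature window (intersected with the global
    window).  Components are returned warmest-first.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    bounds = dict(bounds or {})
    data_lo = float(s.T_grid.min())
    data_hi = float(s.T_grid.max())
    mode_lo, mode_hi = bounds.get(
        "modes",
        (max(DEFAULT_MODE_BOUNDS[0], data_lo), min(DEFAULT_MODE_BOUNDS[1], data_hi)),
    )
    s_lo, s_hi = bounds.get("spreads", DEFAULT_SPREAD_BOUNDS)
    de_bounds = (
        [(mode_lo, mode_hi)] * p
        + [(np.log10(s_lo), np.log10(s_hi))] * p
        + [(0.01, 1.0)] * p
    )
    obj = _objective(s.T_grid, s.log10_Nm, p)
    rng = np.random.SeedSequence(seed)
    best = None
    converged = False
    for child in rng.spawn(restarts):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        res = differential_evolution(
            obj,
            de_bounds,
            seed=sub_seed,
            maxiter=maxiter,
            popsize=popsize,
            tol=1e-12,
            init="sobol",
            vectorized=True,
            updating="deferred",
            polish=True,
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    modes, spreads, weights = (arr.ravel() for arr in _unpack(best.x[:, None], p))
    n_tot = 10.0 ** _optimal_log10_ntot(s.T_grid, s.log10_Nm, modes, spreads, weights)
    m = SubpopulationMixture(
        weights=weights,
        modes=modes,
        spreads=spreads,
        n_tot=n_tot,
        mse=float(best.fun),
    )
    m.converged = converged
    return m.sorted_warmest_first()


def select_components(
    s: SmoothedSpectrum,
    p_max: int,
    seed: int,
    weight_floor: float = WEIGHT_FLOOR,
    merge_tol: float = 0.1,
    **fit_kwargs,
) -> SubpopulationMixture:
    """Fit p = 1..p_max and return the lowest-MSE model, pruned.

    Components with weight below ``weight_floor`` are discarded (weights
    renormalized) and components whose modes coincide within ``merge_tol``
    degC are merged (weight-averaged) — stacked duplicates are a flat
    direction of the fit, not extra subpopulations.  The MSE ladder over p
    is attached to the result.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    ladder = {}
    fits = {}
    ss = np.random.SeedSequence(seed)
    for p, child in zip(range(1, p_max + 1), ss.spawn(p_max)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        m = fit_mixture(s, p, seed=sub_seed, **fit_kwargs)
        ladder[p] = m.mse
        fits[p] = m
    best_p = min(ladder, key=ladder.get)
    m = fits[best_p]
    keep = m.weights >= weight_floor
    if not np.all(keep) and keep.sum() >= 1:
        m = SubpopulationMixture(
            weights=m.weights[keep] / m.weights[keep].sum(),
            modes=m.modes[keep],
            spreads=m.spreads[keep],
            n_tot=m.n_tot,
            mse=m.mse,
        )
    m = _merge_close_components(m, merge_tol)
    m.mse_ladder = ladder
    return m.sorted_warmest_first()


def _merge_close_components(m: SubpopulationMixture, tol: float) -> SubpopulationMixture:
    """Merge components whose modes coincide within ``tol`` degC."""
    order = np.argsort(-m.modes)
    w, mo, sp = m.weights[order], m.modes[order], m.spreads[order]
    out_w, out_mo, out_sp = [w[0]], [mo[0]], [sp[0]]
    for i in range(1, len(w)):
        if abs(mo[i] - out_mo[-1]) < tol:
            tot = out_w[-1] + w[i]
            out_mo[-1] = (out_w[-1] * out_mo[-1] + w[i] * mo[i]) / tot
            out_sp[-1] = (out_w[-1] * out_sp[-1] + w[i] * sp[i]) / tot
            out_w[-1] = tot
        else:
            out_w.append(w[i])
            out_mo.append(mo[i])
            out_sp.append(sp[i])
    return SubpopulationMixture(
        weights=np.array(out_w) / np.sum(out_w),
        modes=np.array(out_mo),
        spreads=np.array(out_sp),
        n_tot=m.n_tot,
        mse=m.mse,
        mse_ladder=dict(m.mse_ladder),
        converged=m.converged,
    )


def differential(m: SubpopulationMixture, T_grid) -> np.ndarray:
    """Normalized differential freezing spectrum n_m(T) on a grid.

    n_m(T) = sum_i c_i N(T; T_mode,i, s_i); integrates to 1 over the real
    line and equals -d/dT [N_m(T)/N_tot].
    """
    return np.asarray(m.pdf(np.asarray(T_grid, dtype=float)))
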