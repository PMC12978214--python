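"""Gaussian-subpopulation model of characteristic ice-nucleation temperatures.

The underlying distribution P_u(T) of characteristic freezing temperatures of
all ice nucleators (INs) in a sample is modelled as a linear combination of p
normalized Gaussians, each subpopulation i having a weight c_i (sum to 1), a
modal freezing temperature T_mode,i (degC) and a spread s_i (degC).  The total
IN concentration N_tot (INs per mg) scales the mixture's survival function
into the cumulative spectrum N_m(T).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

WEIGHT_TOL = 1e-9


@dataclass
class SubpopulationMixture:
    """p Gaussian subpopulations plus a total IN concentration.

    Parameters
    ----------
    weights : array of fractions c_i, summing to 1 within 1e-9.
    modes : modal freezing temperatures T_mode,i in degC.
    spreads : Gaussian spreads s_i in degC, strictly positive.
    n_tot : total number of INs per mg of sample.
    mse : optional fit quality (mean squared error on the fitted scale).
    mse_ladder : optional map p -> best MSE, recorded by model selection.
    """

    weights: np.ndarray
    modes: np.ndarray
    spreads: np.ndarray
    n_tot: float
    mse: float | None = None
    mse_ladder: dict = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.modes = np.atleast_1d(np.asarray(self.modes, dtype=float))
        self.spreads = np.atleast_1d(np.asarray(self.spreads, dtype=float))
        if not (self.weights.shape == self.modes.shape == self.spreads.shape):
            raise ValueError("weights, modes and spreads must have equal length")
        if self.weights.size < 1:
            raise ValueError("need at least one subpopulation")
        if not np.all(np.isfinite(self.weights)) or not np.all(
            np.isfinite(self.modes)
        ) or not np.all(np.isfinite(self.spreads)):
            raise ValueError("non-finite mixture parameters")
        if self.n_tot < 0 or not np.isfinite(self.n_tot):
            raise ValueError("n_tot must be finite and >= 0")
        if np.any(self.spreads <= 0):
            raise ValueError("spreads must be > 0")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")
        if abs(self.weights.sum() - 1.0) > WEIGHT_TOL:
            raise ValueError("weights must sum to 1")

    @property
    def p(self) -> int:
        """Number of subpopulations."""
        return self.weights.size

    def survival(self, T) -> np.ndarray | float:
        """Fraction F_u(T) of INs with characteristic temperature >= T.

        F_u(T) = sum_i c_i * Phi((T_mode,i - T) / s_i), with Phi the standard
        normal CDF.  Tends to 0 far above all modes and to 1 far below.
        """
        T = np.asarray(T, dtype=float)
        Tv = np.atleast_1d(T).ravel()
        z = (self.modes[:, None] - Tv[None, :]) / self.spreads[:, None]
        out = self.weights @ ndtr(z)
        return float(out[0]) if T.ndim == 0 else out.reshape(T.shape)

    def pdf(self, T) -> np.ndarray | float:
        """Normalized density of characteristic temperatures, P_u(T)."""
        T = np.asarray(T, dtype=float)
        Tv = np.atleast_1d(T).ravel()
        z = (Tv[None, :] - self.modes[:, None]) / self.spreads[:, None]
        dens = np.exp(-0.5 * z**2) / (np.sqrt(2 * np.pi) * self.spreads[:, None])
        out = self.weights @ dens
        return float(out[0]) if T.ndim == 0 else out.reshape(T.shape)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw characteristic temperatures from P_u(T)."""
        comp = rng.choice(self.p, size=size, p=self.weights / self.weights.sum())
        return rng.normal(self.modes[comp], self.spreads[comp])

    def sorted_warmest_first(self) -> "SubpopulationMixture":
        """Return a copy with components ordered by decreasing mode."""
        order = np.argsort(-self.modes)
        return SubpopulationMixture(
            weights=self.weights[order],
            modes=self.modes[order],
            spreads=self.spreads[order],
            n_tot=self.n_tot,
            mse=self.mse,
            mse_ladder=dict(self.mse_ladder),
            converged=self.converged,
        )

    def to_dict(self) -> dict:
        return {
            "p": int(self.p),
            "c": self.weights.tolist(),
            "T_mode": self.modes.tolist(),
            "s": self.spreads.tolist(),
            "N_tot": float(self.n_tot),
            "mse": None if self.mse is None else float(self.mse),
            "mse_ladder": {str(k): float(v) for k, v in self.mse_ladder.items()},
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubpopulationMixture":
        m = cls(
            weights=np.asarray(d["c"], dtype=float),
            modes=np.asarray(d["T_mode"], dtype=float),
            spreads=np.asarray(d["s"], dtype=float),
            n_tot=float(d["N_tot"]),
            mse=d.get("mse"),
        )
        m.mse_ladder = {int(k): float(v) for k, v in d.get("mse_ladder", {}).items()}
        m.converged = bool(d.get("converged", True))
        return m
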