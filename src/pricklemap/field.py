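"""Inhibitor-field model of prickle positioning on a stem.

Leaf primordia emerge around the shoot apical meristem at a constant
divergence angle ``Phi`` (by default the golden angle) once per plastochron
``T``, and each secretes a diffusible inhibitor of prickle initiation.  At
diffusive equilibrium the inhibitor arriving from one primordium on the
circular priming zone follows an (unnormalised) von Mises profile
``k(t) * exp(m(t) * cos(phi - phi_i))``, where

* ``k(t)`` is a piecewise-linear secretion schedule rising from ``T_a`` to a
  peak of 1 at ``T_b`` and falling to zero at ``T_c``;
* ``m(t) = max(alpha * t + beta, 0)`` is the von Mises concentration, growing
  linearly as the primordium is carried away from the apex at velocity
  ``alpha`` (a sharper angular footprint for a more distant source).

Only the three primordia nearest in time (n-1, n, n+1) can overlap the
priming circle, so the total field is a three-term superposition.  Prickle
density is proportional to the reciprocal of the total inhibitor intensity,
sampled on an ``N_d x N_d`` lattice over one plastochron / internode.

All angles in this module are radians and time is in units of ``T = 1``;
degree <-> radian conversion happens at the package boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "GOLDEN_ANGLE_RAD",
    "GOLDEN_ANGLE_DEG",
    "RED_QUEEN_PARAMS",
    "PAIRED_PATTERN_PARAMS",
    "ModelParams",
    "GridKind",
    "DensityGrid",
    "secretion_rate",
    "concentration_param",
    "primordium_intensity",
    "total_intensity",
    "model_density_grid",
]

#: Golden angle 2*pi*(1 - 1/golden_ratio) ~ 2.39996 rad ~ 137.5 deg.
GOLDEN_ANGLE_RAD = 2.0 * math.pi * (1.0 - 2.0 / (1.0 + math.sqrt(5.0)))
GOLDEN_ANGLE_DEG = math.degrees(GOLDEN_ANGLE_RAD)

# Exponent clamp: keeps k * exp(m cos phi) finite for the extreme parameter
# values a quasi-Newton line search may probe.  Far above anything reachable
# with printed-scale parameters, so it never affects a feasible fit.
_EXP_CLAMP = 700.0


@dataclass(frozen=True)
class ModelParams:
    """The five free parameters of the inhibitor-field model.

    Parameters
    ----------
    alpha : float
        Radial velocity of primordium displacement from the apex; scales how
        quickly the von Mises concentration grows with time.  Must be > 0.
    beta : float
        Concentration offset: ``m(0) = max(beta, 0)``.
    T_a, T_b, T_c : float
        Start, peak and end of inhibitor secretion, in plastochron units.
        Constrained to ``T_a < T_b < T_c``, ``-T <= T_a`` and
        ``0 < T_c <= 2 T`` so that only the three nearest primordia ever
        contribute to the priming circle.
    T : float
        Plastochron, the unit of model time.  Fixed to 1.
    Phi : float
        Divergence angle between successive primordia, radians.  Defaults to
        the golden angle.
    """

    alpha: float
    beta: float
    T_a: float
    T_b: float
    T_c: float
    T: float = 1.0
    Phi: float = GOLDEN_ANGLE_RAD

    def __post_init__(self) -> None:
        violations = self.violated_constraints()
        if violations:
            raise ValueError(
                "invalid model parameters: " + "; ".join(violations)
            )

    def violated_constraints(self) -> list[str]:
        """Return human-readable descriptions of every violated constraint."""
        out = []
        if not self.alpha > 0:
            out.append(f"alpha > 0 (got alpha={self.alpha})")
        if not self.T_a < self.T_b:
            out.append(f"T_a < T_b (got T_a={self.T_a}, T_b={self.T_b})")
        if not self.T_b < self.T_c:
            out.append(f"T_b < T_c (got T_b={self.T_b}, T_c={self.T_c})")
        if not -self.T <= self.T_a:
            out.append(f"-T <= T_a (got T_a={self.T_a}, T={self.T})")
        if not 0 < self.T_c <= 2 * self.T:
            out.append(f"0 < T_c <= 2T (got T_c={self.T_c}, T={self.T})")
        if not self.T > 0:
            out.append(f"T > 0 (got T={self.T})")
        return out

    @property
    def vector(self) -> np.ndarray:
        """The free parameters as ``[alpha, beta, T_a, T_b, T_c]``."""
        return np.array([self.alpha, self.beta, self.T_a, self.T_b, self.T_c])

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "T_a": self.T_a,
            "T_b": self.T_b,
            "T_c": self.T_c,
            "T": self.T,
            "Phi": self.Phi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {k: float(v) for k, v in d.items() if k in
                 ("alpha", "beta", "T_a", "T_b", "T_c", "T", "Phi")}
        return cls(**known)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


#: Optimised parameter set reported for the dispersed single-peak pattern of
#: R. hybrida 'Red Queen' stems.
RED_QUEEN_PARAMS = ModelParams(alpha=0.267, beta=0.139,
                               T_a=-0.909, T_b=0.071, T_c=1.661)

#: Optimised parameter set reported for the paired, leaf-flanking pattern
#: typified by A. seyal and R. hirtula.
PAIRED_PATTERN_PARAMS = ModelParams(alpha=0.044, beta=0.102,
                                    T_a=0.109, T_b=1.419, T_c=1.925)


class GridKind(str, Enum):
    MODEL = "model_density"
    KDE = "kde_density"


@dataclass
class DensityGrid:
    """Density values on the (phi, t) lattice.

    ``values[i, j]`` is the density at ``phi_axis[i]`` (radians, half-open
    over ``[0, 2*pi)``) and ``t_axis[j]`` (half-open over ``[0, T)``); the
    t axis is identified with the relative internode height h.
    """

    values: np.ndarray
    phi_axis: np.ndarray
    t_axis: np.ndarray
    kind: GridKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.phi_axis = np.asarray(self.phi_axis, dtype=float)
        self.t_axis = np.asarray(self.t_axis, dtype=float)
        self.kind = GridKind(self.kind)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.phi_axis), len(self.t_axis)):
            raise ValueError("values shape does not match axes")
        if not (np.all(np.diff(self.phi_axis) > 0)
                and np.all(np.diff(self.t_axis) > 0)):
            raise ValueError("axes must be strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("values must be finite and non-negative")

    @property
    def N_d(self) -> int:
        return len(self.phi_axis)

    @property
    def cell_area(self) -> float:
        """Area of one lattice cell (uniform spacing on both axes)."""
        return float(self.phi_axis[1] - self.phi_axis[0]) * \
            float(self.t_axis[1] - self.t_axis[0])

    def total_mass(self) -> float:
        """Riemann-sum integral of the grid over its rectangle."""
        return float(self.values.sum() * self.cell_area)

    def phi_marginal(self) -> np.ndarray:
        """Density aggregated over the t axis (one value per phi node)."""
        return self.values.sum(axis=1)

    def argmax_phi_deg(self) -> float:
        """phi (degrees, in [0, 360)) maximising the t-aggregated density."""
        return float(np.degrees(self.phi_axis[np.argmax(self.phi_marginal())]))


def same_axes(a: DensityGrid, b: DensityGrid, atol: float = 1e-9) -> bool:
    return (a.values.shape == b.values.shape
            and np.allclose(a.phi_axis, b.phi_axis, atol=atol)
            and np.allclose(a.t_axis, b.t_axis, atol=atol))


# ---------------------------------------------------------------------------
# raw kernels (plain floats/arrays; used directly by the optimizer where
# intermediate iterates may sit on the constraint boundary)

def _secretion_raw(t, T_a: float, T_b: float, T_c: float):
    """Piecewise-linear secretion schedule; zero-width limbs treated as empty."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    if T_b > T_a:
        rise = (T_a < t) & (t < T_b)
        out = np.where(rise, (t - T_a) / (T_b - T_a), out)
    if T_c > T_b:
        fall = (T_b <= t) & (t < T_c)
        out = np.where(fall, (T_c - t) / (T_c - T_b), out)
    return out


def _concentration_raw(t, alpha: float, beta: float):
    return np.maximum(alpha * np.asarray(t, dtype=float) + beta, 0.0)


def _total_intensity_raw(phi, t, alpha, beta, T_a, T_b, T_c,
                         Phi=GOLDEN_ANGLE_RAD, T=1.0):
    """Three-primordium superposition; vectorised over phi and t."""
    phi = np.asarray(phi, dtype=float)
    t = np.asarray(t, dtype=float)
    total = np.zeros(np.broadcast(phi, t).shape)
    for dt, dphi in ((-T, -Phi), (0.0, 0.0), (T, Phi)):
        k = _secretion_raw(t + dt, T_a, T_b, T_c)
        m = _concentration_raw(t + dt, alpha, beta)
        arg = np.minimum(m * np.cos(phi + dphi), _EXP_CLAMP)
        total = total + k * np.exp(arg)
    return total


# ---------------------------------------------------------------------------
# public model surface

def secretion_rate(t, params: ModelParams):
    """k(t): 0 outside (T_a, T_c), rising linearly to 1 at T_b, then falling.

    Continuous and bounded in [0, 1]; a total function of t.
    """
    return _secretion_raw(t, params.T_a, params.T_b, params.T_c)


def concentration_param(t, params: ModelParams):
    """m(t) = max(alpha * t + beta, 0): the von Mises concentration."""
    return _concentration_raw(t, params.alpha, params.beta)


def primordium_intensity(phi, t, phi_source, params: ModelParams):
    """Inhibitor intensity from a single primordium at direction phi_source.

    ``k(t) * exp(m(t) * cos(phi - phi_source))`` -- an unnormalised von Mises
    profile; the normalising constant is deliberately omitted (the downstream
    Pearson cost is scale-invariant).
    """
    k = secretion_rate(t, params)
    m = concentration_param(t, params)
    arg = np.minimum(m * np.cos(np.asarray(phi, dtype=float)
                                - phi_source), _EXP_CLAMP)
    return k * np.exp(arg)


def total_intensity(phi, t, params: ModelParams):
    """Total inhibitor f(phi, t) from primordia n-1, n and n+1.

    Equals ``k(t-T) e^{m(t-T) cos(phi-Phi)} + k(t) e^{m(t) cos(phi)}
    + k(t+T) e^{m(t+T) cos(phi+Phi)}``; 2*pi-periodic in phi.
    """
    return _total_intensity_raw(phi, t, params.alpha, params.beta,
                                params.T_a, params.T_b, params.T_c,
                                Phi=params.Phi, T=params.T)


def model_density_grid(params: ModelParams, N_d: int = 100,
                       epsilon: float = 1e-12, *,
                       reciprocal: bool = True,
                       corotating_frame: bool = True) -> DensityGrid:
    """Sample the model prickle density on the N_d x N_d (phi, t) lattice.

    ``values[i, j] = 1 / max(f(phi_i, t_j), epsilon)`` with
    ``phi_i = 2 pi i / N_d`` and ``t_j = j T / N_d`` -- the reciprocal of the
    total inhibitor intensity, floored at ``epsilon`` so every entry stays
    finite even where all three secretion windows vanish.

    Parameters
    ----------
    corotating_frame : bool
        If True (default), the field is evaluated at ``phi + Phi * t / T``,
        i.e. in the frame of the leaf-connecting spline that the measured
        relative angle phi is defined against; the spline rotates by one
        divergence angle per internode while the primordia stay fixed.  If
        False, phi is measured from the fixed direction of the n-th
        primordium.
    reciprocal : bool
        If False, return the raw intensity f itself instead of 1/f.
    """
    if N_d < 2:
        raise ValueError("N_d must be >= 2")
    phi_axis = 2.0 * np.pi * np.arange(N_d) / N_d
    t_axis = params.T * np.arange(N_d) / N_d
    P, Tt = np.meshgrid(phi_axis, t_axis, indexing="ij")
    if corotating_frame:
        P = P + params.Phi * Tt / params.T
    f = _total_intensity_raw(P, Tt, params.alpha, params.beta,
                             params.T_a, params.T_b, params.T_c,
                             Phi=params.Phi, T=params.T)
    values = 1.0 / np.maximum(f, epsilon) if reciprocal else f
    return DensityGrid(values=values, phi_axis=phi_axis, t_axis=t_axis,
                       kind=GridKind.MODEL)
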