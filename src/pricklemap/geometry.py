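"""Leaf-relative stem geometry.

Raw measurements on a shoot are (theta, H) pairs: the angle around the stem
in degrees and the height along the shoot in millimetres, for every leaf and
every mature prickle.  This module converts them into the leaf-relative
coordinates the patterning analysis runs in:

* leaf angles are unwrapped to cumulative angles ``theta_c = theta + 360 N``
  so the spiral phyllotaxis becomes a monotone curve on the (theta_c, H)
  plane;
* a cubic spline ``theta_sp(H)`` through the leaf positions defines the
  phyllotactic reference direction at every height;
* each prickle gets a relative angle ``phi = theta_c - theta_sp(H)`` in
  [-90, 270) degrees and a relative height ``h`` in [0, 1] within its
  internode (0 at the lower node, 1 at the upper node).

Left-handed spirals are mirrored first so every stem is analysed in the same
chirality (mean leaf divergence < 180 deg).  Angles are degrees throughout
this module, matching how the measurements are taken.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

__all__ = [
    "MATURITY_MIN_MM",
    "OrganKind",
    "OrganObservation",
    "StemRecord",
    "PhyllotaxisFrame",
    "ProcessedPrickle",
    "mirror_if_left_handed",
    "unwrap_leaf_angles",
    "fit_phyllotaxis_spline",
    "compute_phi",
    "compute_h",
    "divergence_angles",
    "nearest_prickle_distances",
    "layer_split",
    "process_stem",
]

#: Prickles shorter than this are immature and excluded from analysis.
MATURITY_MIN_MM = 5.0

#: Default stem radius (mm) for cylinder-surface distances.
DEFAULT_STEM_RADIUS_MM = 5.0


class OrganKind(str, Enum):
    LEAF = "leaf"
    PRICKLE = "prickle"


@dataclass(frozen=True)
class OrganObservation:
    """One measured organ: kind, angle theta in [0, 360) deg, height H in mm."""

    kind: OrganKind
    theta_deg: float
    H_mm: float
    prickle_height_mm: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", OrganKind(self.kind))
        if not 0.0 <= self.theta_deg < 360.0:
            raise ValueError(f"theta_deg must be in [0, 360): {self.theta_deg}")
        if self.H_mm < 0:
            raise ValueError(f"H_mm must be >= 0: {self.H_mm}")


@dataclass
class StemRecord:
    """Ordered organ observations for one shoot.

    Organs are kept sorted by height (stable for ties); ``mirrored`` records
    whether angles were reflected to normalise chirality.
    """

    stem_id: str
    organs: list[OrganObservation]
    mirrored: bool = False

    def __post_init__(self) -> None:
        self.organs = sorted(self.organs, key=lambda o: o.H_mm)

    @property
    def leaves(self) -> list[OrganObservation]:
        return [o for o in self.organs if o.kind is OrganKind.LEAF]

    @property
    def prickles(self) -> list[OrganObservation]:
        return [o for o in self.organs if o.kind is OrganKind.PRICKLE]


@dataclass
class PhyllotaxisFrame:
    """Interpolating spline through (leaf height, cumulative leaf angle)."""

    leaf_H: np.ndarray
    leaf_theta_c: np.ndarray
    spline: object  # callable H (mm) -> theta_sp (deg)

    @property
    def H_min(self) -> float:
        return float(self.leaf_H[0])

    @property
    def H_max(self) -> float:
        return float(self.leaf_H[-1])

    def __call__(self, H) :
        return self.spline(H)


@dataclass(frozen=True)
class ProcessedPrickle:
    """A prickle in leaf-relative coordinates."""

    phi_deg: float
    h: float
    H_mm: float
    internode_index: int
    source_index: int

    def __post_init__(self) -> None:
        if not -90.0 <= self.phi_deg < 270.0:
            raise ValueError(f"phi_deg out of [-90, 270): {self.phi_deg}")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"h out of [0, 1]: {self.h}")


# ---------------------------------------------------------------------------


def unwrap_leaf_angles(leaf_thetas: Sequence[float]) -> np.ndarray:
    """Cumulative leaf angles theta_c = theta + 360 N, strictly increasing.

    N is the smallest non-negative integer sequence making theta_c strictly
    increasing bottom-to-top; ties between consecutive equal angles are
    broken by incrementing N.  theta_c mod 360 reproduces the input exactly.
    """
    thetas = np.asarray(leaf_thetas, dtype=float)
    if thetas.size == 0:
        raise ValueError("at least one leaf angle required")
    if np.any(thetas < 0) or np.any(thetas >= 360):
        raise ValueError("leaf angles must be in [0, 360)")
    out = np.empty_like(thetas)
    out[0] = thetas[0]
    for i in range(1, len(thetas)):
        n = max(0, math.floor((out[i - 1] - thetas[i]) / 360.0) + 1)
        # guard the float edge where the candidate lands exactly on out[i-1]
        while thetas[i] + 360.0 * n <= out[i - 1]:
            n += 1
        out[i] = thetas[i] + 360.0 * n
    return out


def mirror_if_left_handed(stem: StemRecord) -> StemRecord:
    """Reflect all angles if the leaf spiral is left-handed.

    The spiral is left-handed when the mean leaf-to-leaf divergence of the
    minimally unwrapped angles is >= 180 deg; reflection maps every theta to
    (360 - theta) mod 360 so all stems share one chirality.  Idempotent: a
    record that was already normalised is returned unchanged (reflection can
    leave the mean at exactly 180 deg in degenerate float cases, so the flag,
    not the angle test, guards re-entry).
    """
    if stem.mirrored:
        return stem
    leaves = stem.leaves
    if len(leaves) < 2:
        raise ValueError("insufficient leaves: >= 2 required to determine handedness")
    theta_c = unwrap_leaf_angles([lf.theta_deg for lf in leaves])
    mean_div = float(np.mean(np.diff(theta_c)))
    if mean_div < 180.0:
        return stem
    organs = [replace(o, theta_deg=(360.0 - o.theta_deg) % 360.0)
              for o in stem.organs]
    return StemRecord(stem_id=stem.stem_id, organs=organs, mirrored=True)


def fit_phyllotaxis_spline(leaf_H: Sequence[float],
                           leaf_theta_c: Sequence[float]) -> PhyllotaxisFrame:
    """Natural cubic interpolating spline theta_sp(H) through the leaf knots.

    Passes exactly through every (H, theta_c) pair; with two leaves it
    degenerates to the connecting straight line.
    """
    H = np.asarray(leaf_H, dtype=float)
    tc = np.asarray(leaf_theta_c, dtype=float)
    if H.size < 2:
        raise ValueError("at least 2 leaves required")
    if np.any(np.diff(H) <= 0):
        raise ValueError("leaf heights must be strictly increasing")
    if np.any(np.diff(tc) <= 0):
        raise ValueError("cumulative leaf angles must be strictly increasing")
    if H.size == 2:
        slope = (tc[1] - tc[0]) / (H[1] - H[0])

        def spline(x, H0=H[0], t0=tc[0], s=slope):
            return t0 + s * (np.asarray(x, dtype=float) - H0)
    else:
        spline = CubicSpline(H, tc, bc_type="natural")
    return PhyllotaxisFrame(leaf_H=H, leaf_theta_c=tc, spline=spline)


class OutsideInternodeRange(ValueError):
    """Raised when a prickle height falls outside the leaf span."""


def compute_phi(prickle_theta: float, prickle_H: float,
                frame: PhyllotaxisFrame) -> float:
    """Relative angle phi = (theta + 360 N) - theta_sp(H), in [-90, 270).

    N is the unique integer placing phi in the half-open window; invariant
    under adding any multiple of 360 to the input angle.
    """
    if not frame.H_min <= prickle_H <= frame.H_max:
        raise OutsideInternodeRange(
            f"prickle at H={prickle_H} mm outside internode range "
            f"[{frame.H_min}, {frame.H_max}]")
    raw = float(prickle_theta) - float(frame(prickle_H))
    return raw - 360.0 * math.floor((raw + 90.0) / 360.0)


def compute_h(prickle_H: float, frame: PhyllotaxisFrame) -> tuple[float, int]:
    """Relative height within the flanking internode.

    Returns (h, lower-leaf index) with h = (H - H_low) / (H_up - H_low).
    A prickle exactly at a node belongs to the internode above it (h = 0);
    at the topmost node, where no internode above exists, it is reported as
    h = 1 of the top internode.
    """
    H = float(prickle_H)
    leaf_H = frame.leaf_H
    if not leaf_H[0] <= H <= leaf_H[-1]:
        raise OutsideInternodeRange(
            f"prickle at H={H} mm outside internode range "
            f"[{leaf_H[0]}, {leaf_H[-1]}]")
    idx = int(np.searchsorted(leaf_H, H, side="right")) - 1
    if idx >= len(leaf_H) - 1:  # exactly at the top node
        return 1.0, len(leaf_H) - 2
    h = (H - leaf_H[idx]) / (leaf_H[idx + 1] - leaf_H[idx])
    return float(h), idx


def divergence_angles(frame: PhyllotaxisFrame) -> np.ndarray:
    """Successive leaf-to-leaf divergences (deg); may exceed 270 deg."""
    if len(frame.leaf_theta_c) < 2:
        raise ValueError("at least 2 leaves required")
    return np.diff(frame.leaf_theta_c)


def wrapped_angle_diff_rad(theta1_deg, theta2_deg) -> np.ndarray:
    """Signed angular difference wrapped into (-pi, pi], radians."""
    d = np.deg2rad(np.asarray(theta1_deg, dtype=float)
                   - np.asarray(theta2_deg, dtype=float))
    return np.pi - np.mod(np.pi - d, 2.0 * np.pi)


def nearest_prickle_distances(prickles: Sequence[tuple[float, float]],
                              stem_radius_mm: float = DEFAULT_STEM_RADIUS_MM,
                              ) -> np.ndarray:
    """Nearest-neighbour distance d_pp for each prickle, on the cylinder.

    ``prickles`` is a sequence of (theta_deg, H_mm).  The metric is the
    cylinder-surface Euclidean distance
    ``sqrt(dH^2 + (r * dtheta_wrapped)^2)`` with the angular difference
    wrapped into (-pi, pi].  Fewer than two prickles yields an empty result.
    """
    if stem_radius_mm <= 0:
        raise ValueError("stem_radius_mm must be > 0")
    pts = np.asarray(prickles, dtype=float)
    if pts.ndim != 2 or (pts.size and pts.shape[1] != 2):
        raise ValueError("prickles must be (theta_deg, H_mm) pairs")
    n = len(pts)
    if n < 2:
        return np.empty(0)
    dth = wrapped_angle_diff_rad(pts[:, None, 0], pts[None, :, 0])
    dH = pts[:, None, 1] - pts[None, :, 1]
    dist = np.sqrt(dH ** 2 + (stem_radius_mm * dth) ** 2)
    np.fill_diagonal(dist, np.inf)
    return dist.min(axis=1)


def layer_split(prickles: Sequence[ProcessedPrickle], H_top: float,
                ) -> tuple[list[float], list[float], list[float]]:
    """Split phi samples into bottom / middle / top thirds of the stem.

    Layers partition height as [0, H_top/3), [H_top/3, 2H_top/3),
    [2H_top/3, H_top]; empty layers are allowed.
    """
    if H_top <= 0:
        raise ValueError("H_top must be > 0")
    layers: tuple[list[float], list[float], list[float]] = ([], [], [])
    for p in prickles:
        if p.H_mm < H_top / 3.0:
            layers[0].append(p.phi_deg)
        elif p.H_mm < 2.0 * H_top / 3.0:
            layers[1].append(p.phi_deg)
        else:
            layers[2].append(p.phi_deg)
    return layers


# ---------------------------------------------------------------------------


def build_frame(stem: StemRecord) -> PhyllotaxisFrame:
    """Unwrap the stem's leaf angles and fit the phyllotaxis spline."""
    leaves = stem.leaves
    if len(leaves) < 2:
        raise ValueError("insufficient leaves: >= 2 required")
    theta_c = unwrap_leaf_angles([lf.theta_deg for lf in leaves])
    return fit_phyllotaxis_spline([lf.H_mm for lf in leaves], theta_c)


def process_stem(stem: StemRecord,
                 stem_radius_mm: float = DEFAULT_STEM_RADIUS_MM,
                 ) -> pd.DataFrame:
    """Full geometry pipeline for one stem.

    Mirrors if left-handed, fits the phyllotaxis spline, converts every
    prickle to (phi, h) and attaches nearest-neighbour distances.  Prickles
    outside the leaf span are skipped with a logged warning.  Returns one row
    per processed prickle with columns ``stem_id, phi_deg, h, H_mm,
    internode_index, d_pp_mm``.
    """
    stem = mirror_if_left_handed(stem)
    frame = build_frame(stem)
    prickles = stem.prickles
    kept: list[ProcessedPrickle] = []
    kept_obs = []
    n_skipped = 0
    for i, p in enumerate(prickles):
        try:
            phi = compute_phi(p.theta_deg, p.H_mm, frame)
            h, node = compute_h(p.H_mm, frame)
        except OutsideInternodeRange:
            n_skipped += 1
            continue
        kept.append(ProcessedPrickle(phi_deg=phi, h=h, H_mm=p.H_mm,
                                     internode_index=node, source_index=i))
        kept_obs.append(p)
    if n_skipped:
        logger.warning("stem %s: skipped %d prickle(s) outside the leaf span",
                       stem.stem_id, n_skipped)
    if len(kept_obs) >= 2:
        d_pp = nearest_prickle_distances(
            [(o.theta_deg, o.H_mm) for o in kept_obs], stem_radius_mm)
    else:
        d_pp = np.full(len(kept_obs), np.nan)
    return pd.DataFrame({
        "stem_id": stem.stem_id,
        "phi_deg": [p.phi_deg for p in kept],
        "h": [p.h for p in kept],
        "H_mm": [p.H_mm for p in kept],
        "internode_index": [p.internode_index for p in kept],
        "d_pp_mm": d_pp,
    })
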