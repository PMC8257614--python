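"""Synthetic stems and prickle patterns.

Emulates the statistical structure of real measured shoots so the whole
pipeline is testable without measured data: spiral phyllotaxis with noisy
golden-angle divergence and occasional extreme deviations (> 270 deg),
truncated-normal internode lengths, and prickles drawn from the inhibitor
model's density grid with a hard-core minimum spacing (close prickle pairs
are essentially never observed on real stems).

Sampling from the density is inverse-CDF at the lattice-cell level
(multinomial over cells proportional to density, uniform jitter within the
cell), so the sampler is exactly consistent with the grid density the
fitting module sees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .field import DensityGrid, ModelParams, RED_QUEEN_PARAMS, model_density_grid
from .geometry import (
    OrganKind,
    OrganObservation,
    StemRecord,
    build_frame,
    wrapped_angle_diff_rad,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "generate_stem",
    "sample_prickles",
    "generate_measurements",
    "aseyal_pair_fixture",
    "redqueen_fixture",
]

#: Retries per prickle before dropping it when the hard core rejects.
_REJECTION_BUDGET = 100


@dataclass
class SynthConfig:
    """Study-condition defaults for the synthetic stem generator.

    Divergence is golden-angle on average with 10 deg noise and a 5%
    chance of an extreme internode (uniform in 270-330 deg); internodes
    average 30 +/- 8 mm (truncated > 1 mm), a few prickles per internode,
    and a 5 mm hard-core spacing on a 5 mm-radius stem.
    """

    n_leaves: int = 12
    mean_divergence_deg: float = 137.5
    divergence_sd_deg: float = 10.0
    big_deviation_prob: float = 0.05
    internode_mean_mm: float = 30.0
    internode_sd_mm: float = 8.0
    prickles_per_internode_mean: float = 3.0
    min_spacing_mm: float = 5.0
    stem_radius_mm: float = 5.0
    params: ModelParams = field(default_factory=lambda: RED_QUEEN_PARAMS)
    N_d: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        if not 0 <= self.big_deviation_prob <= 1:
            raise ValueError("big_deviation_prob must be in [0, 1]")
        if self.min_spacing_mm < 0 or self.stem_radius_mm <= 0:
            raise ValueError("spacing must be >= 0 and radius > 0")
        if (self.divergence_sd_deg < 0 or self.internode_sd_mm < 0
                or self.prickles_per_internode_mean < 0
                or self.internode_mean_mm <= 0):
            raise ValueError("negative noise / rate parameters")


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def generate_stem(config: SynthConfig, stem_id: str = "synthetic",
                  ) -> StemRecord:
    """Generate the leaves of one spiral-phyllotaxis stem.

    Divergences are Normal(mean, sd), replaced with probability
    ``big_deviation_prob`` by a uniform draw in (270, 330) deg; internode
    lengths are Normal truncated to > 1 mm.  Deterministic under the seed.
    """
    rng, _ = _rngs(config.seed, 2)
    theta = float(rng.uniform(0.0, 360.0))
    H = 0.0
    organs = [OrganObservation(OrganKind.LEAF, theta % 360.0, H)]
    for _ in range(config.n_leaves - 1):
        if rng.uniform() < config.big_deviation_prob:
            div = rng.uniform(270.0, 330.0)
        else:
            div = rng.normal(config.mean_divergence_deg,
                             config.divergence_sd_deg)
        length = rng.normal(config.internode_mean_mm, config.internode_sd_mm)
        while length <= 1.0:
            length = rng.normal(config.internode_mean_mm,
                                config.internode_sd_mm)
        theta += div
        H += length
        organs.append(OrganObservation(OrganKind.LEAF, theta % 360.0, H))
    return StemRecord(stem_id=stem_id, organs=organs)


def _sample_from_grid(grid: DensityGrid, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw n (phi_deg in [-90, 270), h) points from a density grid.

    Cell-level inverse CDF: cells are chosen with probability proportional
    to their density value (uniform cell areas), then jittered uniformly
    within the cell.
    """
    p = grid.values.ravel()
    p = p / p.sum()
    cells = rng.choice(p.size, size=n, p=p)
    i, j = np.unravel_index(cells, grid.values.shape)
    dphi = 2.0 * np.pi / grid.N_d
    dt = float(grid.t_axis[1] - grid.t_axis[0])
    phi = grid.phi_axis[i] + rng.uniform(0.0, dphi, size=n)
    h = grid.t_axis[j] + rng.uniform(0.0, dt, size=n)
    phi_deg = np.degrees(phi) % 360.0
    phi_deg = np.where(phi_deg >= 270.0, phi_deg - 360.0, phi_deg)
    return np.column_stack([phi_deg, h])


def sample_prickles(stem: StemRecord, config: SynthConfig) -> StemRecord:
    """Add model-sampled prickles to a stem, with hard-core thinning.

    Per internode the prickle count is Poisson; (phi, h) positions come from
    the model density grid and are mapped to (theta, H) through the stem's
    own phyllotaxis spline (the exact inverse of the measurement transform).
    A candidate closer than ``min_spacing_mm`` (cylinder-surface distance) to
    an accepted prickle is resampled, up to a bounded attempt budget.
    """
    frame = build_frame(stem)
    _, rng = _rngs(config.seed, 2)
    grid = model_density_grid(config.params, N_d=config.N_d)
    accepted: list[tuple[float, float]] = [
        (p.theta_deg, p.H_mm) for p in stem.prickles]
    new: list[OrganObservation] = []
    n_dropped = 0
    leaf_H = frame.leaf_H
    for k in range(len(leaf_H) - 1):
        H_low, H_up = float(leaf_H[k]), float(leaf_H[k + 1])
        count = int(rng.poisson(config.prickles_per_internode_mean))
        for _ in range(count):
            placed = False
            for _attempt in range(_REJECTION_BUDGET):
                phi_deg, h = _sample_from_grid(grid, 1, rng)[0]
                H = H_low + h * (H_up - H_low)
                theta = (float(frame(H)) + phi_deg) % 360.0
                if _hard_core_ok(theta, H, accepted, config):
                    accepted.append((theta, H))
                    new.append(OrganObservation(OrganKind.PRICKLE, theta, H))
                    placed = True
                    break
            if not placed:
                n_dropped += 1
    if n_dropped:
        logger.warning(
            "hard-core rejection budget exhausted for %d prickle(s); "
            "generated fewer than requested", n_dropped)
    return StemRecord(stem_id=stem.stem_id, organs=stem.organs + new,
                      mirrored=stem.mirrored)


def _hard_core_ok(theta: float, H: float,
                  accepted: list[tuple[float, float]],
                  config: SynthConfig) -> bool:
    if config.min_spacing_mm == 0 or not accepted:
        return True
    pts = np.asarray(accepted, dtype=float)
    dth = wrapped_angle_diff_rad(theta, pts[:, 0])
    d = np.sqrt((H - pts[:, 1]) ** 2 + (config.stem_radius_mm * dth) ** 2)
    return bool(d.min() >= config.min_spacing_mm)


def generate_measurements(config: SynthConfig, n_stems: int = 1,
                          ) -> list[StemRecord]:
    """Generate complete stems (leaves + prickles); one sub-seed per stem."""
    stems = []
    for i, ss in enumerate(np.random.SeedSequence(config.seed).spawn(n_stems)):
        sub = SynthConfig(**{**config.__dict__,
                             "seed": int(ss.generate_state(1)[0] % 2**31)})
        stem = generate_stem(sub, stem_id=f"stem{i + 1}")
        stems.append(sample_prickles(stem, sub))
    return stems


def aseyal_pair_fixture() -> np.ndarray:
    """The literature-derived A. seyal paired pattern: two prickles flanking
    the leaf base at h = 0.95, phi = +/-60 deg."""
    return np.array([[60.0, 0.95], [-60.0, 0.95]])


def redqueen_fixture(seed: int, n: int) -> np.ndarray:
    """n (phi_deg, h) points sampled from the reference 'Red Queen' density.

    A reproducible synthetic stand-in for a dispersed single-peak pattern
    (no measured multi-stem dataset is distributed with the package).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = model_density_grid(RED_QUEEN_PARAMS)
    return _sample_from_grid(grid, n, np.random.default_rng(seed))
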