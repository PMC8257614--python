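"""CSV and JSON interchange.

Measurement CSV (one row per organ): ``stem_id, kind, theta_deg, H_mm,
prickle_height_mm`` -- the last column optional / blank for leaves.
Prickles below the 5 mm maturity threshold are dropped on read, with a
logged count.  Processed CSV (one row per prickle): ``stem_id, phi_deg, h,
H_mm, internode_index, d_pp_mm``.  Density grids are written as a CSV
matrix with phi in degrees down the first column and t across the header.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .field import DensityGrid, GridKind
from .geometry import (
    MATURITY_MIN_MM,
    OrganKind,
    OrganObservation,
    StemRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_processed",
    "write_processed",
    "grid_to_csv",
    "grid_from_csv",
]

MEASUREMENT_COLUMNS = ["stem_id", "kind", "theta_deg", "H_mm"]


def read_measurements(path, maturity_min_mm: float = MATURITY_MIN_MM,
                      ) -> list[StemRecord]:
    """Read a measurement CSV into per-stem records.

    Immature prickles (``prickle_height_mm`` present and below the
    threshold) are dropped with a logged count; stems keep input order.
    """
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement CSV missing column(s): {missing}")
    if "prickle_height_mm" in df.columns:
        ph = pd.to_numeric(df["prickle_height_mm"], errors="coerce")
        drop = (df["kind"] == OrganKind.PRICKLE.value) & ph.notna() \
            & (ph < maturity_min_mm)
        if drop.any():
            logger.info("maturity filter: dropped %d prickle(s) below "
                        "%g mm", int(drop.sum()), maturity_min_mm)
            df = df[~drop]
    stems: list[StemRecord] = []
    for stem_id, group in df.groupby("stem_id", sort=False):
        organs = []
        for row in group.itertuples(index=True):
            try:
                ph_val = getattr(row, "prickle_height_mm", None)
                ph_val = None if ph_val is None or pd.isna(ph_val) \
                    else float(ph_val)
                organs.append(OrganObservation(
                    kind=OrganKind(str(row.kind)),
                    theta_deg=float(row.theta_deg),
                    H_mm=float(row.H_mm),
                    prickle_height_mm=ph_val))
            except (ValueError, TypeError) as exc:
                raise ValueError(
                    f"measurement CSV row {row.Index + 2}: {exc}") from exc
        stems.append(StemRecord(stem_id=str(stem_id), organs=organs))
    return stems


def write_measurements(stems: list[StemRecord], path) -> None:
    rows = [{
        "stem_id": s.stem_id,
        "kind": o.kind.value,
        "theta_deg": o.theta_deg,
        "H_mm": o.H_mm,
        "prickle_height_mm": o.prickle_height_mm,
    } for s in stems for o in s.organs]
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS + ["prickle_height_mm"],
                 ).to_csv(path, index=False)


def write_processed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_processed(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("phi_deg", "h"):
        if col not in df.columns:
            raise ValueError(f"processed CSV missing column: {col}")
    return df


def grid_to_csv(grid: DensityGrid, path) -> None:
    """Write a density grid: phi (deg) in the index, t across the header."""
    df = pd.DataFrame(grid.values,
                      index=np.round(np.degrees(grid.phi_axis), 10),
                      columns=np.round(grid.t_axis, 10))
    df.index.name = f"phi_deg[{grid.kind.value}]"
    df.to_csv(path)


def grid_from_csv(path) -> DensityGrid:
    df = pd.read_csv(path, index_col=0)
    kind = GridKind.MODEL
    name = df.index.name or ""
    if "[" in name:
        kind = GridKind(name.split("[", 1)[1].rstrip("]"))
    return DensityGrid(values=df.to_numpy(dtype=float),
                       phi_axis=np.deg2rad(df.index.to_numpy(dtype=float)),
                       t_axis=df.columns.to_numpy(dtype=float),
                       kind=kind)
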