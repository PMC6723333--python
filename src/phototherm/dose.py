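"""CEM43 thermal dose and cell-survival mapping.

The cumulative-equivalent-minutes metric normalizes an arbitrary
temperature history to an equivalent duration at 43 degC:

    CEM43 = sum_i  t_i * R^(43 - T_i)        [minutes]

with T_i the interval-average temperature and R the per-degree
compensation factor — the standard isoeffect constants R = 0.5 above
43 degC and R = 0.25 below are the defaults.  Dose maps to an estimated
cell kill through a single-exponential survival curve calibrated to 10%
survival after 120 equivalent minutes:

    S(dose) = exp(-lambda * dose),  lambda = ln(10) / 120 min^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bioheat import ThermalHistory
from .geometry import Entity, VoxelGrid

__all__ = [
    "R_ABOVE",
    "R_BELOW",
    "SURVIVAL_LAMBDA",
    "DoseCube",
    "KillMap",
    "cem43_increment",
    "accumulate_cem43",
    "survival_fraction",
    "kill_map",
    "line_profile",
    "mask_region",
]

R_ABOVE = 0.5
R_BELOW = 0.25
#: ln(10)/120: survival decay rate per CEM43 minute, anchored at
#: S(120 min) = 0.10.
SURVIVAL_LAMBDA = np.log(10.0) / 120.0


@dataclass
class DoseCube:
    """Per-voxel CEM43 thermal dose (minutes)."""

    grid: VoxelGrid
    cem43: np.ndarray


@dataclass
class KillMap:
    """Per-voxel estimated cell death (percent, 0-100)."""

    grid: VoxelGrid
    death_pct: np.ndarray


def cem43_increment(
    T_avg, dt_min, R_above: float = R_ABOVE, R_below: float = R_BELOW
):
    """Equivalent minutes at 43 degC contributed by one interval.

    ``T_avg`` may be a scalar or array (degC); ``dt_min`` is the
    interval length in minutes.
    """
    T = np.asarray(T_avg, dtype=float)
    if np.any(np.asarray(dt_min) < 0):
        raise ValueError("interval length must be >= 0")
    R = np.where(T >= 43.0, R_above, R_below)
    out = dt_min * R ** (43.0 - T)
    return float(out) if np.isscalar(T_avg) else out


def accumulate_cem43(
    history: ThermalHistory,
    R_above: float = R_ABOVE,
    R_below: float = R_BELOW,
    T_cutoff: float | None = None,
) -> DoseCube:
    """Integrate CEM43 over a temperature history, voxel by voxel.

    Each interval between consecutive snapshots contributes
    dt * R^(43 - T) with T the trapezoidal (midpoint-of-endpoints)
    average of the bounding snapshots.  ``T_cutoff`` optionally zeroes
    contributions from intervals whose average stays below it.
    """
    if len(history.times) < 2:
        raise ValueError("need at least two snapshots to accumulate dose")
    t = np.asarray(history.times)
    if np.any(np.diff(t) <= 0):
        raise ValueError("snapshot times must be strictly increasing")
    dose = np.zeros(history.grid.shape, dtype=np.float64)
    for i in range(len(t) - 1):
        dt_min = (t[i + 1] - t[i]) / 60.0
        T_avg = 0.5 * (
            history.snapshots[i].astype(np.float64)
            + history.snapshots[i + 1].astype(np.float64)
        )
        inc = cem43_increment(T_avg, dt_min, R_above, R_below)
        if T_cutoff is not None:
            inc = np.where(T_avg >= T_cutoff, inc, 0.0)
        dose += inc
    return DoseCube(grid=history.grid, cem43=dose)


def survival_fraction(cem43, lam: float = SURVIVAL_LAMBDA):
    """Surviving cell fraction for a given CEM43 dose (minutes)."""
    dose = np.asarray(cem43, dtype=float)
    if np.any(dose < 0):
        raise ValueError("cem43 must be >= 0")
    out = np.exp(-lam * dose)
    return float(out) if np.isscalar(cem43) else out


def kill_map(dose: DoseCube, lam: float = SURVIVAL_LAMBDA) -> KillMap:
    """Estimated percent cell death per voxel from the dose cube."""
    return KillMap(
        grid=dose.grid, death_pct=100.0 * (1.0 - survival_fraction(dose.cem43, lam))
    )


def line_profile(
    cube: np.ndarray,
    grid: VoxelGrid,
    axis: int,
    point_mm,
) -> tuple[np.ndarray, np.ndarray]:
    """Samples of a voxel cube along one axis through a given point.

    Returns (positions_mm, values) ordered by increasing coordinate;
    ``point_mm`` fixes the two transverse coordinates.
    """
    idx = list(grid.point_to_index(point_mm))
    positions = grid.axis_centers(axis)
    slicer: list = idx
    slicer[axis] = slice(None)
    return positions, np.asarray(cube)[tuple(slicer)]


def mask_region(
    cube: np.ndarray,
    entity: Entity | None,
    grid: VoxelGrid,
    sentinel: float = np.nan,
) -> np.ndarray:
    """Copy of ``cube`` with voxels inside ``entity`` set to ``sentinel``.

    Used to blank the tumour so damage to the surrounding normal tissue
    stands out.  ``entity=None`` (or an entity containing no voxel
    centres) leaves the cube unchanged; masking is idempotent.
    """
    out = np.array(cube, dtype=float, copy=True)
    if entity is None:
        return out
    centers = grid.centers().reshape(-1, 3)
    inside = entity.contains(centers).reshape(grid.shape)
    out[inside] = sentinel
    return out
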