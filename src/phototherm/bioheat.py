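"""Explicit finite-difference solver of the Pennes bioheat equation.

    rho c dT/dt = div(k grad T) - B (T - T_a) + Q

on the transport voxel grid, with Q the absorbed optical power density
(W/m^3) held constant over the heating window (constant illumination).
B = c_b * w_b * rho_b lumps the perfusion heat sink.

Boundary handling follows the voxel cell-type map:

* ``AIR`` voxels take no part in conduction and hold the initial
  temperature — the tissue-air interface is adiabatic (insulated skin
  surface), enforced by mirroring across faces shared with air;
* ``CLAMPED`` tissue voxels stay at the arterial temperature (far-field
  body temperature on the lateral/deep faces of the tissue block);
* ``ACTIVE`` voxels evolve by forward Euler with a 7-point Laplacian.

Perfusion applies only in tissue.  Time steps obey the explicit
stability bound dt <= safety * rho c / (2 k sum(1/h_i^2) + B).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .geometry import BioheatParams, VoxelGrid
from .transport import DepositionCube

__all__ = [
    "AIR",
    "ACTIVE",
    "CLAMPED",
    "TemperatureField",
    "ThermalHistory",
    "perfusion_coefficient",
    "stable_timestep",
    "build_cell_types",
    "step",
    "run_heating",
]

AIR = np.uint8(0)
ACTIVE = np.uint8(1)
CLAMPED = np.uint8(2)


@dataclass
class TemperatureField:
    """Per-voxel temperature (degC) at a single instant."""

    grid: VoxelGrid
    T: np.ndarray
    time: float = 0.0

    @classmethod
    def uniform(cls, grid: VoxelGrid, T0: float = 37.0) -> "TemperatureField":
        return cls(grid=grid, T=np.full(grid.shape, float(T0)), time=0.0)


@dataclass
class ThermalHistory:
    """Temperature snapshots at strictly increasing times.

    Snapshots are stored float32 (millikelvin-level, ample for dose
    work); the solver itself steps in float64.
    """

    grid: VoxelGrid
    times: list[float] = field(default_factory=list)
    snapshots: list[np.ndarray] = field(default_factory=list)
    T_initial: float = 37.0

    def append(self, t: float, T: np.ndarray) -> None:
        if self.times and t <= self.times[-1]:
            raise ValueError("snapshot times must be strictly increasing")
        self.times.append(float(t))
        self.snapshots.append(np.asarray(T, dtype=np.float32).copy())

    def at_time(self, t: float) -> np.ndarray:
        """Snapshot recorded at time ``t`` (exact match required)."""
        for ti, Ti in zip(self.times, self.snapshots):
            if np.isclose(ti, t):
                return Ti
        raise KeyError(f"no snapshot at t = {t} s (have {self.times})")

    def peak_rise(self, mask: np.ndarray | None = None) -> float:
        """Maximum temperature rise over all snapshots (within ``mask``)."""
        best = 0.0
        for T in self.snapshots:
            sub = T[mask] if mask is not None else T
            if sub.size:
                best = max(best, float(sub.max()) - self.T_initial)
        return best

    def rise_at(self, t: float, mask: np.ndarray | None = None) -> float:
        """Maximum rise within ``mask`` at the snapshot recorded at ``t``."""
        T = self.at_time(t)
        sub = T[mask] if mask is not None else T
        return float(sub.max()) - self.T_initial

    def probe(self, point: Sequence[float]) -> np.ndarray:
        """Temperature time series at the voxel containing ``point``."""
        idx = self.grid.point_to_index(point)
        return np.array([T[idx] for T in self.snapshots])


def perfusion_coefficient(params: BioheatParams) -> float:
    """Perfusion heat-sink coefficient B = c_b * w_b * rho_b, W/(m^3 K)."""
    return params.B


def stable_timestep(
    params: BioheatParams,
    voxel_edges_mm: Sequence[float],
    safety: float = 0.9,
    cap: float = 20.0,
) -> float:
    """Largest forward-Euler step (s) satisfying the stability bound.

    dt <= safety * rho c / (2 k sum(1/h^2) + B); an unconditionally
    stable degenerate case (k = 0, B = 0) is capped at ``cap`` seconds.
    """
    h = np.asarray(voxel_edges_mm, dtype=float) * 1e-3  # mm -> m
    if np.any(h <= 0):
        raise ValueError("voxel edges must be positive")
    denom = 2.0 * params.k * float(np.sum(1.0 / h**2)) + params.B
    if denom <= 0.0:
        return cap
    return min(safety * params.rho * params.c / denom, cap)


def build_cell_types(
    material_index: np.ndarray,
    air_ids: Sequence[int] = (0,),
    up_axis: int = 2,
) -> np.ndarray:
    """Classify voxels for the heat stepper from the voxelized scene.

    Tissue voxels bordering air through their upward face only (the
    skin surface) stay ACTIVE — that interface is adiabatic.  Tissue
    voxels bordering air through any lateral or downward face, or
    sitting on the domain boundary, are CLAMPED at the far-field body
    temperature.
    """
    is_air = np.isin(material_index, np.asarray(list(air_ids)))
    cell = np.where(is_air, AIR, ACTIVE).astype(np.uint8)

    tissue = ~is_air
    clamp = np.zeros_like(tissue)
    for axis in range(3):
        for sign in (+1, -1):
            if axis == up_axis and sign == +1:
                continue  # upward face: adiabatic skin surface
            neigh_air = np.ones_like(tissue)  # out-of-domain counts as air
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if sign == +1:
                dst[axis] = slice(0, -1)
                src[axis] = slice(1, None)
            else:
                dst[axis] = slice(1, None)
                src[axis] = slice(0, -1)
            neigh_air[tuple(dst)] = is_air[tuple(src)]
            clamp |= tissue & neigh_air
    cell[clamp] = CLAMPED
    return cell


@njit(cache=True, fastmath=True)
def _step_kernel(T, Tn, Q, cell, dx2, dy2, dz2, k, rcp, Bcoef, Ta, dt):
    nx, ny, nz = T.shape
    for i in range(nx):
        for j in range(ny):
            for l in range(nz):
                if cell[i, j, l] != 1:
                    Tn[i, j, l] = T[i, j, l]
                    continue
                Tc = T[i, j, l]
                # mirror across air faces / domain edges (zero flux)
                Txm = T[i - 1, j, l] if i > 0 and cell[i - 1, j, l] != 0 else Tc
                Txp = T[i + 1, j, l] if i < nx - 1 and cell[i + 1, j, l] != 0 else Tc
                Tym = T[i, j - 1, l] if j > 0 and cell[i, j - 1, l] != 0 else Tc
                Typ = T[i, j + 1, l] if j < ny - 1 and cell[i, j + 1, l] != 0 else Tc
                Tzm = T[i, j, l - 1] if l > 0 and cell[i, j, l - 1] != 0 else Tc
                Tzp = T[i, j, l + 1] if l < nz - 1 and cell[i, j, l + 1] != 0 else Tc
                lap = (
                    (Txm - 2.0 * Tc + Txp) / dx2
                    + (Tym - 2.0 * Tc + Typ) / dy2
                    + (Tzm - 2.0 * Tc + Tzp) / dz2
                )
                Tn[i, j, l] = Tc + dt / rcp * (
                    k * lap - Bcoef * (Tc - Ta) + Q[i, j, l]
                )


def step(
    field_: TemperatureField,
    Q: np.ndarray,
    params: BioheatParams,
    dt: float,
    cell: np.ndarray,
    out: np.ndarray | None = None,
) -> TemperatureField:
    """One forward-Euler update of the temperature field.

    Raises if ``dt`` exceeds the explicit stability bound (checked
    without the safety margin).
    """
    bound = stable_timestep(params, field_.grid.edges, safety=1.0, cap=np.inf)
    if dt > bound * (1.0 + 1e-12):
        raise ValueError(f"dt = {dt} s exceeds the stability bound {bound} s")
    h = field_.grid.edges * 1e-3
    Tn = out if out is not None else np.empty_like(field_.T)
    _step_kernel(
        field_.T,
        Tn,
        Q,
        cell,
        h[0] ** 2,
        h[1] ** 2,
        h[2] ** 2,
        params.k,
        params.rho * params.c,
        params.B,
        params.T_a,
        dt,
    )
    return TemperatureField(grid=field_.grid, T=Tn, time=field_.time + dt)


def run_heating(
    Q: DepositionCube | np.ndarray,
    params: BioheatParams,
    duration: float,
    record_interval: float = 20.0,
    extra_record_times: Sequence[float] = (),
    grid: VoxelGrid | None = None,
    cell: np.ndarray | None = None,
    T0: float = 37.0,
) -> ThermalHistory:
    """Integrate the bioheat equation under constant illumination.

    Snapshots are recorded at t = 0, every ``record_interval`` seconds,
    any ``extra_record_times``, and at ``duration``; intervals are
    subdivided so each landing is exact while every step respects the
    stability bound.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if isinstance(Q, DepositionCube):
        grid = grid or Q.grid
        if cell is None:
            cell = build_cell_types(Q.material_index)
        q = Q.q
    else:
        if grid is None:
            raise ValueError("grid is required when Q is a bare array")
        q = np.asarray(Q, dtype=float)
        if cell is None:
            cell = np.full(grid.shape, ACTIVE, dtype=np.uint8)

    record = {0.0, float(duration)}
    record.update(float(t) for t in extra_record_times if 0.0 < t <= duration)
    nrec = int(np.floor(duration / record_interval))
    record.update(record_interval * k for k in range(1, nrec + 1))
    times = sorted(record)

    dt_max = stable_timestep(params, grid.edges)
    hist = ThermalHistory(grid=grid, T_initial=T0)
    fld = TemperatureField.uniform(grid, T0)
    hist.append(0.0, fld.T)
    buf = np.empty_like(fld.T)
    for t_prev, t_next in zip(times[:-1], times[1:]):
        span = t_next - t_prev
        nsub = max(1, int(np.ceil(span / dt_max - 1e-12)))
        dt = span / nsub
        for _ in range(nsub):
            nxt = step(fld, q, params, dt, cell, out=buf)
            buf = fld.T  # reuse the old buffer for the next step
            fld = nxt
        fld = TemperatureField(grid=grid, T=fld.T, time=t_next)  # exact time
        hist.append(t_next, fld.T)
    return hist
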