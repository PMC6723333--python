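"""Finite-difference bioheat solver: stability, limits, conservation."""

import numpy as np
import pytest

from phototherm.bioheat import (
    ACTIVE,
    AIR,
    CLAMPED,
    TemperatureField,
    build_cell_types,
    perfusion_coefficient,
    run_heating,
    stable_timestep,
    step,
)
from phototherm.geometry import BioheatParams, VoxelGrid
from phototherm.validation import heat_kernel_oracle, perfusion_ode_oracle


class TestPerfusionCoefficient:
    def test_standard_values_product(self):
        assert perfusion_coefficient(BioheatParams()) == pytest.approx(
            38_340.2, rel=1e-9
        )

    def test_zero_and_linearity(self):
        assert perfusion_coefficient(BioheatParams(w_b=0.0)) == 0.0
        b1 = perfusion_coefficient(BioheatParams(w_b=0.005))
        b2 = perfusion_coefficient(BioheatParams(w_b=0.01))
        assert b2 == pytest.approx(2 * b1, rel=1e-12)


class TestStableTimestep:
    def test_plug_in_value(self):
        # isotropic 0.1 mm voxels with standard tissue constants:
        # 0.9 * (1079*3540) / (6*0.53/1e-8 + 38340.2) ~ 0.01081 s
        dt = stable_timestep(BioheatParams(), (0.1, 0.1, 0.1))
        assert dt == pytest.approx(0.010809, rel=1e-3)

    def test_halving_dx_quarters_dt(self):
        p = BioheatParams(w_b=1e-9)  # make perfusion negligible
        dt1 = stable_timestep(p, (0.1, 0.1, 0.1))
        dt2 = stable_timestep(p, (0.05, 0.05, 0.05))
        assert dt1 / dt2 == pytest.approx(4.0, rel=1e-6)

    def test_degenerate_case_capped(self):
        p = BioheatParams(k=1e-300, w_b=0.0)
        assert stable_timestep(p, (0.1, 0.1, 0.1), cap=20.0) == 20.0


class TestStep:
    def test_equilibrium_is_fixed_point(self):
        grid = VoxelGrid.cube(1.0, 8)
        p = BioheatParams()
        f = TemperatureField.uniform(grid, 37.0)
        cell = np.ones(grid.shape, np.uint8)
        out = step(f, np.zeros(grid.shape), p, stable_timestep(p, grid.edges), cell)
        assert np.array_equal(out.T, f.T)

    def test_unstable_dt_rejected(self):
        grid = VoxelGrid.cube(1.0, 8)
        p = BioheatParams()
        f = TemperatureField.uniform(grid)
        cell = np.ones(grid.shape, np.uint8)
        with pytest.raises(ValueError):
            step(f, np.zeros(grid.shape), p, 10.0, cell)

    def test_perfusion_relaxation_matches_ode(self):
        # uniform field and source: conduction is inert, leaving the
        # perfusion ODE T(t) = Ta + (Q/B)(1 - exp(-B t / rho c))
        grid = VoxelGrid.cube(1.0, 6)
        p = BioheatParams()
        Q = np.full(grid.shape, 2e6)
        hist = run_heating(Q, p, duration=120.0, record_interval=30.0,
                           grid=grid, cell=np.ones(grid.shape, np.uint8))
        for t in (30.0, 60.0, 120.0):
            got = float(hist.at_time(t)[3, 3, 3])
            assert got == pytest.approx(perfusion_ode_oracle(p, 2e6, t), abs=0.05)

    def test_discrete_energy_conservation_insulated(self):
        # B = 0, insulated boundaries: energy grows by exactly sum(Q V dt)
        grid = VoxelGrid.cube(1.0, 10)
        p = BioheatParams(w_b=0.0)
        Q = np.zeros(grid.shape)
        Q[4:6, 4:6, 4:6] = 7e6
        cell = np.ones(grid.shape, np.uint8)
        dt = stable_timestep(p, grid.edges)
        f = TemperatureField.uniform(grid)
        E0 = p.rho * p.c * f.T.sum() * grid.voxel_volume_m3
        n = 40
        for _ in range(n):
            f = step(f, Q, p, dt, cell)
        E1 = p.rho * p.c * f.T.sum() * grid.voxel_volume_m3
        expect = Q.sum() * grid.voxel_volume_m3 * dt * n
        assert (E1 - E0) == pytest.approx(expect, rel=1e-9)

    def test_maximum_principle_without_sources(self, rng):
        grid = VoxelGrid.cube(1.0, 9)
        p = BioheatParams(w_b=0.0)
        T0 = 37.0 + rng.uniform(0.0, 5.0, grid.shape)
        f = TemperatureField(grid=grid, T=T0.copy())
        cell = np.ones(grid.shape, np.uint8)
        dt = stable_timestep(p, grid.edges)
        for _ in range(20):
            f = step(f, np.zeros(grid.shape), p, dt, cell)
            assert f.T.max() <= T0.max() + 1e-9
            assert f.T.min() >= T0.min() - 1e-9

    def test_point_spike_converges_to_heat_kernel(self):
        # B = 0, Q = 0: a point excess relaxes toward the Gaussian kernel;
        # the L2 error against the oracle shrinks under grid refinement
        p = BioheatParams(w_b=0.0)
        D = p.k / (p.rho * p.c)
        t_end = 0.5
        errs = []
        for n in (15, 31):
            grid = VoxelGrid.cube(2.0, n)
            mid = (n - 1) // 2
            T = np.full(grid.shape, 37.0)
            # unit "excess energy per rho c": amplitude 1/V so that the
            # spatial integral of (T - 37) is 1 m^3 K at any resolution
            T[mid, mid, mid] += 1.0 / grid.voxel_volume_m3
            f = TemperatureField(grid=grid, T=T)
            cell = np.ones(grid.shape, np.uint8)
            dt = stable_timestep(p, grid.edges)
            nstep = int(np.ceil(t_end / dt))
            for _ in range(nstep):
                f = step(f, np.zeros(grid.shape), p, t_end / nstep, cell)
            r = np.linalg.norm(grid.centers() * 1e-3, axis=-1)  # mm -> m
            oracle = heat_kernel_oracle(D, t_end, r)
            excess = f.T - 37.0
            errs.append(
                np.linalg.norm(excess - oracle) / np.linalg.norm(oracle)
            )
        assert errs[1] < errs[0]
        assert errs[1] < 0.15


class TestCellTypes:
    def test_skin_surface_adiabatic_sides_clamped(self):
        # tissue block occupying the lower-centre of a small air box
        mat = np.zeros((7, 7, 7), dtype=np.uint8)
        mat[2:5, 2:5, 1:5] = 1  # tissue, top face at z-index 4
        cell = build_cell_types(mat)
        assert cell[0, 0, 0] == AIR
        assert cell[3, 3, 3] == ACTIVE
        # top tissue voxels see air only upward -> stay active
        assert cell[3, 3, 4] == ACTIVE
        # lateral and bottom tissue faces are clamped
        assert cell[2, 3, 3] == CLAMPED
        assert cell[3, 4, 3] == CLAMPED
        assert cell[3, 3, 1] == CLAMPED

    def test_clamped_voxels_hold_body_temperature(self):
        mat = np.zeros((7, 7, 7), dtype=np.uint8)
        mat[2:5, 2:5, 1:5] = 1
        cell = build_cell_types(mat)
        p = BioheatParams(w_b=0.0)
        grid = VoxelGrid.cube(1.0, 7)
        Q = np.where(mat == 1, 5e7, 0.0)
        hist = run_heating(Q, p, duration=5.0, record_interval=5.0,
                           grid=grid, cell=cell)
        T = hist.snapshots[-1]
        assert T[2, 3, 3] == pytest.approx(37.0)
        assert T[3, 3, 3] > 37.0
        assert T[0, 0, 0] == pytest.approx(37.0)  # air untouched


class TestRunHeating:
    def test_snapshot_schedule(self):
        grid = VoxelGrid.cube(1.0, 5)
        p = BioheatParams()
        hist = run_heating(np.zeros(grid.shape), p, duration=10.0,
                           record_interval=4.0, extra_record_times=[0.5],
                           grid=grid, cell=np.ones(grid.shape, np.uint8))
        assert hist.times == [0.0, 0.5, 4.0, 8.0, 10.0]
        assert np.all(hist.snapshots[0] == 37.0)

    def test_monotone_approach_to_plateau(self):
        # constant uniform heating: temperature rises monotonically and
        # the increments shrink (approach to the perfusion plateau)
        grid = VoxelGrid.cube(1.0, 5)
        p = BioheatParams()
        Q = np.full(grid.shape, 1e6)
        hist = run_heating(Q, p, duration=400.0, record_interval=100.0,
                           grid=grid, cell=np.ones(grid.shape, np.uint8))
        series = [float(T[2, 2, 2]) for T in hist.snapshots]
        diffs = np.diff(series)
        assert np.all(diffs > 0)
        assert np.all(np.diff(diffs) < 0)
        assert series[-1] < p.T_a + 1e6 / p.B  # below the Q/B plateau
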