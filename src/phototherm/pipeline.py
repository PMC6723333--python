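"""End-to-end pipeline: transport -> bioheat -> thermal dose.

``run_pipeline`` executes the three stages for one config, writes every
cube in the sidecar format plus probe/profile CSVs, and records a
manifest (versions, seed, checksums) so any output is reproducible
byte-for-byte from (config, seed, code version).
"""

from __future__ import annotations

import json
import logging
import platform
import time
from pathlib import Path

import numpy as np

from . import __version__
from .bioheat import ThermalHistory, run_heating
from .config import (
    RunConfig,
    build_bioheat_params,
    build_scene,
    build_source,
    save_config,
)
from .dose import accumulate_cem43, kill_map, line_profile, mask_region
from .geometry import Scene
from .io import sha256_file, write_csv, write_cube
from .transport import DepositionCube, RunSpec, run_transport

log = logging.getLogger("phototherm")

__all__ = ["PipelineError", "run_pipeline", "tumour_mask"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage."""


def tumour_mask(scene: Scene, cube: DepositionCube,
                entity_name: str = "tumour") -> np.ndarray:
    """Boolean voxel mask of one entity, from the run's voxelization."""
    ascending = [e.name for e in reversed(scene.entities)]
    if entity_name not in ascending:
        raise ValueError(f"no entity named {entity_name!r}")
    return cube.material_index == (ascending.index(entity_name) + 1)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # tag the failing stage
                raise PipelineError(f"[{name}] {exc}") from exc
            log.info("stage %s finished in %.1f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("transport")
def _run_transport_stage(config: RunConfig, scene: Scene) -> DepositionCube:
    source = build_source(config)
    spec = RunSpec(
        L=config.source.power_W,
        N=config.transport.packets,
        seed=config.transport.seed,
        w_min=config.transport.w_min,
        p_survive=config.transport.p_survive,
    )
    cube = run_transport(scene, source, spec)
    log.info(
        "transport: N=%d absorbed=%.4g escaped=%.4g (sum/N=%.6f)",
        spec.N, cube.absorbed_weight, cube.escaped_weight,
        (cube.absorbed_weight + cube.escaped_weight) / spec.N,
    )
    return cube


@_stage("heat")
def _run_heat_stage(config: RunConfig, cube: DepositionCube) -> ThermalHistory:
    params = build_bioheat_params(config)
    return run_heating(
        cube,
        params,
        duration=config.heat.duration_s,
        record_interval=config.heat.record_interval_s,
        extra_record_times=config.heat.extra_record_times_s,
        T0=config.heat.T_a,
    )


@_stage("dose")
def _run_dose_stage(config: RunConfig, history: ThermalHistory):
    dcube = accumulate_cem43(history, R_above=config.dose.r_above,
                             R_below=config.dose.r_below)
    return dcube, kill_map(dcube)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run transport -> heat -> dose; write artifacts; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    scene = build_scene(config)
    cube = _run_transport_stage(config, scene)
    history = _run_heat_stage(config, cube)
    dcube, kmap = _run_dose_stage(config, history)

    grid = cube.grid
    mask = tumour_mask(scene, cube)
    files: list[Path] = []

    meta = {
        "seed": config.transport.seed,
        "packets": config.transport.packets,
        "power_W": config.source.power_W,
        "escaped_weight": cube.escaped_weight,
        "absorbed_weight": cube.absorbed_weight,
    }
    files.append(write_cube(outdir / "q", cube.q, grid, "W/m^3", meta))
    files.append(write_cube(outdir / "temperature_final",
                            history.snapshots[-1].astype(np.float64), grid,
                            "degC", {"time_s": history.times[-1]}))
    files.append(write_cube(outdir / "cem43", dcube.cem43, grid, "min"))
    death = kmap.death_pct
    if config.dose.mask_tumour:
        tum = next(e for e in scene.entities if e.name == "tumour")
        death = mask_region(death, tum, grid)
    files.append(write_cube(outdir / "death_pct", death, grid, "%"))

    # probe CSV: in-tumour centroid and peak temperature over time
    centroid = [float(np.mean(grid.axis_centers(a)[np.any(mask, axis=tuple(
        {0, 1, 2} - {a}))])) for a in range(3)]
    ci = grid.point_to_index(centroid)
    rows = [
        (t, float(T[ci]), float(T[mask].max()) if mask.any() else float("nan"))
        for t, T in zip(history.times, history.snapshots)
    ]
    files.append(write_csv(outdir / "probe.csv",
                           ["time_s", "T_centroid_degC", "T_peak_degC"], rows))

    # vertical line profiles through the beam axis
    axis_pt = (0.0, 0.0, 0.0)
    for label, arr in (("q", cube.q), ("death_pct", death)):
        pos, vals = line_profile(arr, grid, axis=2, point_mm=axis_pt)
        files.append(write_csv(outdir / f"profile_{label}.csv",
                               ["z_mm", label], zip(pos, vals)))

    save_config(config, outdir / "config.json")
    files.append(outdir / "config.json")

    manifest = {
        "package": "phototherm",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.transport.seed,
        "stages": ["transport", "heat", "dose"],
        "checksums": {f.name: sha256_file(f) for f in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
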