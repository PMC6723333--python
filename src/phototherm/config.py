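"""Run configuration: validated models, TOML/JSON loading, scene building.

A run is described by one declarative config: a materials table
(optical coefficients in cm^-1, with optional composites that sum the
coefficients of two listed materials), a list of mesh entities with
priorities, the disc source, the voxel grid, and the transport / heat /
dose stage parameters.  The packaged default reproduces the built-in
skin-cancer scenario: a 10 mm air-filled domain, a 6 mm flesh cube, a
nanorod-infused oblate-spheroid tumour (1 mm diameter, 0.5 mm height)
1 mm below the skin surface, and a 1 W disc source of radius 3 mm.
"""

from __future__ import annotations

import json
import tomllib
from importlib import resources
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, field_validator, model_validator

from .geometry import (
    DiscSource,
    Entity,
    OpticalMaterial,
    BioheatParams,
    Scene,
    VoxelGrid,
    composite_material,
    load_stl,
    make_box,
    make_disc_source,
    make_oblate_spheroid,
)

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "default_config",
    "control_variant",
    "build_scene",
    "build_source",
    "build_bioheat_params",
]


class MaterialConfig(BaseModel):
    """One row of the materials table (coefficients in cm^-1)."""

    mu_a: float = Field(ge=0)
    mu_s: float = Field(ge=0)
    g: float = Field(default=0.9, ge=-1.0, le=1.0)
    n: float = Field(default=1.38, ge=1.0)
    composite_of: list[str] | None = None


class EntityConfig(BaseModel):
    name: str
    shape: Literal["box", "oblate_spheroid", "stl"]
    material: str
    priority: int = 0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    extents: tuple[float, float, float] | None = None      # box
    semi_axes: tuple[float, float, float] | None = None    # spheroid
    subdivisions: int = Field(default=4, ge=1)
    path: str | None = None                                 # stl

    @model_validator(mode="after")
    def _shape_args(self) -> "EntityConfig":
        need = {"box": "extents", "oblate_spheroid": "semi_axes", "stl": "path"}
        if getattr(self, need[self.shape]) is None:
            raise ValueError(f"entity {self.name!r}: shape {self.shape!r} "
                             f"requires {need[self.shape]!r}")
        return self


class SourceConfig(BaseModel):
    center: tuple[float, float, float]
    radius_mm: float = Field(gt=0)
    power_W: float = Field(gt=0)
    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    n_fan: int = Field(default=16, ge=3)


class GridConfig(BaseModel):
    half_extent_mm: float = Field(default=5.0, gt=0)
    n_cells: int = Field(default=201, ge=1)


class TransportConfig(BaseModel):
    packets: int = Field(ge=1)
    seed: int  # mandatory: every run must be reproducible
    w_min: float = Field(default=1e-4, ge=0)
    p_survive: float = Field(default=0.1, gt=0, lt=1)


class HeatConfig(BaseModel):
    duration_s: float = Field(default=600.0, gt=0)
    record_interval_s: float = Field(default=20.0, gt=0)
    extra_record_times_s: list[float] = Field(default_factory=lambda: [1.0])
    rho: float = Field(default=1079.0, gt=0)
    c: float = Field(default=3540.0, gt=0)
    k: float = Field(default=0.53, gt=0)
    rho_b: float = Field(default=1060.0, gt=0)
    c_b: float = Field(default=3617.0, gt=0)
    w_b: float = Field(default=0.01, ge=0)
    T_a: float = 37.0


class DoseConfig(BaseModel):
    r_above: float = Field(default=0.5, gt=0, lt=1)
    r_below: float = Field(default=0.25, gt=0, lt=1)
    survival_anchor_minutes: float = Field(default=120.0, gt=0)
    survival_anchor_fraction: float = Field(default=0.10, gt=0, lt=1)
    mask_tumour: bool = False


class RunConfig(BaseModel):
    """Fully validated description of one end-to-end run."""

    materials: dict[str, MaterialConfig]
    entities: list[EntityConfig]
    ambient: str = "air"
    source: SourceConfig
    grid: GridConfig = GridConfig()
    transport: TransportConfig
    heat: HeatConfig = HeatConfig()
    dose: DoseConfig = DoseConfig()

    @field_validator("entities")
    @classmethod
    def _unique_names(cls, v: list[EntityConfig]) -> list[EntityConfig]:
        names = [e.name for e in v]
        if len(set(names)) != len(names):
            raise ValueError("entity names must be unique")
        return v

    @model_validator(mode="after")
    def _references(self) -> "RunConfig":
        known = set(self.materials)
        if self.ambient not in known:
            raise ValueError(f"ambient material {self.ambient!r} is not defined")
        for ent in self.entities:
            if ent.material not in known:
                raise ValueError(
                    f"entity {ent.name!r} references unknown material "
                    f"{ent.material!r}"
                )
        for name, mat in self.materials.items():
            for part in mat.composite_of or ():
                if part not in known:
                    raise ValueError(
                        f"composite material {name!r} references unknown "
                        f"material {part!r}"
                    )
        return self


# ---------------------------------------------------------------------------
# Loading / saving
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML or JSON run configuration."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back to disk as JSON (loadable by load_config)."""
    Path(path).write_text(json.dumps(config.model_dump(), indent=2))


def default_config() -> RunConfig:
    """The packaged default scenario (nanorod-infused tumour)."""
    ref = resources.files("phototherm").joinpath("data/default.toml")
    data = tomllib.loads(ref.read_text())
    return RunConfig.model_validate(data)


def control_variant(config: RunConfig, tumour_entity: str = "tumour",
                    material: str = "tumour_tissue") -> RunConfig:
    """Copy of a config with the tumour entity set to plain tumour tissue."""
    out = config.model_copy(deep=True)
    for ent in out.entities:
        if ent.name == tumour_entity:
            ent.material = material
            break
    else:
        raise ValueError(f"no entity named {tumour_entity!r}")
    return RunConfig.model_validate(out.model_dump())


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _resolve_materials(config: RunConfig) -> dict[str, OpticalMaterial]:
    out: dict[str, OpticalMaterial] = {}
    for name, m in config.materials.items():
        if m.composite_of is None:
            out[name] = OpticalMaterial(name=name, mu_a=m.mu_a, mu_s=m.mu_s,
                                        g=m.g, n=m.n)
    for name, m in config.materials.items():
        if m.composite_of is not None:
            if len(m.composite_of) != 2:
                raise ValueError(f"composite {name!r} must list exactly two parts")
            base, additive = (out[p] for p in m.composite_of)
            out[name] = composite_material(base, additive, name=name)
    return out


def build_scene(config: RunConfig) -> Scene:
    """Compile the config into a mesh scene on its voxel grid."""
    mats = _resolve_materials(config)
    grid = VoxelGrid.cube(config.grid.half_extent_mm, config.grid.n_cells)
    entities = []
    for e in config.entities:
        if e.shape == "box":
            mesh = make_box(e.center, e.extents)
        elif e.shape == "oblate_spheroid":
            mesh = make_oblate_spheroid(e.center, e.semi_axes, e.subdivisions)
        else:
            mesh = load_stl(e.path)
        entities.append(
            Entity(name=e.name, mesh=mesh, material=mats[e.material],
                   priority=e.priority)
        )
    return Scene(domain=grid, ambient=mats[config.ambient], entities=entities)


def build_source(config: RunConfig) -> DiscSource:
    s = config.source
    return make_disc_source(
        center=s.center, radius=s.radius_mm, n_fan=s.n_fan,
        power=s.power_W, direction=s.direction,
    )


def build_bioheat_params(config: RunConfig) -> BioheatParams:
    h = config.heat
    return BioheatParams(rho=h.rho, c=h.c, k=h.k, rho_b=h.rho_b,
                         c_b=h.c_b, w_b=h.w_b, T_a=h.T_a)
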