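"""Run configuration: validated blocks, presets M1-M21, (de)serialization.

Model names follow the study grid: ``M1``-``M7`` are healthy-tissue
models with SAC reversal potentials -10 ... -70 mV and a 10 mm SAC
radius; ``_r9/_r8/_r7`` suffixes shrink the radius; ``M8``-``M14`` carry
conduction slowing with suffixes like ``_40g`` (40 % slowing, global) or
``_20l`` (20 %, SAC region only); ``M15``-``M21`` add fibrotic
microstructure (clefts) in the SAC region.  Unknown keys are rejected;
configurations round-trip losslessly through YAML.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .cell.protocols import CellParams, init_and_prepace
from .fibrosis import generate_clefts
from .geometry import (DEFAULT_ROOT_LAYOUT, default_sac_center,
                       make_geometry, place_root_points, tag_sac_region)
from .heterogeneity import (ConductivitySpec, HeterogeneityField,
                            apply_cv_slowing, build_iks_field,
                            calibrate_conductivity)
from .sac import SACParams
from .solver import SolverConfig


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryConfig(_Block):
    kind: str = "slab"
    dimensions_mm: list[float] = Field(default=[60.0, 60.0, 12.0])
    spacing_um: float = 500.0
    sac_radius_mm: float = 10.0
    shell_width_mm: float = 1.0
    sac_center_mm: list[float] | None = None
    sac_transmural_frac: float = 0.5
    endo_layer_mm: float = 1.0
    fiber_rotation: bool = True

    @field_validator("kind")
    @classmethod
    def _kind(cls, v):
        if v not in ("rod", "sheet", "slab"):
            raise ValueError("kind must be rod|sheet|slab")
        return v


class CellConfig(_Block):
    variant: str = "epi"
    reference_iks_scale: float = 1.0
    ab_range: tuple[float, float] = (1.0, 2.0)
    tm_range: tuple[float, float] = (1.0, 2.0)
    n_prepace_beats: int = 50


class SACConfig(_Block):
    e_sac_mv: float = -10.0
    g_target: float = 0.1
    tau_ms: float = 1.8
    eps_switch: float = 1e-13

    @field_validator("e_sac_mv")
    @classmethod
    def _esac(cls, v):
        if not -70.0 <= v <= -10.0:
            raise ValueError(
                "e_sac_mv outside the study range [-70, -10] mV")
        return v


class FibrosisConfig(_Block):
    cv_slowing: float = 0.0
    scope: str = "global"
    clefts: bool = False

    @field_validator("cv_slowing")
    @classmethod
    def _frac(cls, v):
        if not 0.0 <= v < 1.0:
            raise ValueError("cv_slowing must lie in [0, 1)")
        return v

    @field_validator("scope")
    @classmethod
    def _scope(cls, v):
        if v not in ("global", "sac_region"):
            raise ValueError("scope must be global|sac_region")
        return v


class ConductivityConfig(_Block):
    """Monodomain conductivities (S/m).

    The defaults reproduce the package's rod calibration at 530 um
    spacing against 0.56 / 0.21 / 2.0 m/s; set ``calibrate`` to rerun
    the calibration for the configured spacing instead.
    """

    sigma_l: float = 0.21681667956192494
    sigma_t: float = 0.06292728038084087
    endo_sigma: float = 2.031222111005504
    chi: float = 1400.0
    cm: float = 1.0
    calibrate: bool = False


class ProtocolConfig(_Block):
    bcl: float = 500.0
    n_prepace_beats: int = 3
    stim_amplitude: float = 100.0
    stim_duration: float = 1.0
    root_layout: list[tuple[float, float, float]] = Field(
        default=list(DEFAULT_ROOT_LAYOUT))

    @field_validator("bcl")
    @classmethod
    def _bcl(cls, v):
        if v <= 300:
            raise ValueError("bcl must exceed the longest APD (300 ms)")
        return v


class SolverBlock(_Block):
    dt_reaction: float = 0.02
    dt_diffusion: float = 0.1
    output_interval: float = 1.0
    frame_interval: float = 5.0
    upstroke_threshold: float = -20.0
    implicit: bool = True
    use_table: bool = True
    record_frames: bool = False


class ModelConfig(_Block):
    name: str = "custom"
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    cell: CellConfig = Field(default_factory=CellConfig)
    sac: SACConfig = Field(default_factory=SACConfig)
    fibrosis: FibrosisConfig = Field(default_factory=FibrosisConfig)
    conductivity: ConductivityConfig = Field(
        default_factory=ConductivityConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    solver: SolverBlock = Field(default_factory=SolverBlock)
    seed: int = 0


class StudyConfig(_Block):
    models: list[ModelConfig] = Field(default_factory=list)
    onset_start: float = 1.0
    onset_stop: float = 350.0
    onset_step: float = 1.0
    post_window_ms: float = 1050.0
    assess_sustained: bool = True


def parse_and_validate(text: str) -> ModelConfig:
    """Parse a YAML model configuration; presets expand from ``name``."""
    data = yaml.safe_load(text) or {}
    name = data.get("name")
    if name and _PRESET_RE.match(name):
        base = preset(name).model_dump()
        base.update({k: v for k, v in data.items() if k != "name"})
        base["name"] = name
        return ModelConfig.model_validate(base)
    return ModelConfig.model_validate(data)


def serialize(cfg: ModelConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(), sort_keys=True)


def config_hash(cfg: ModelConfig) -> str:
    return hashlib.sha256(serialize(cfg).encode()).hexdigest()[:16]


_PRESET_RE = re.compile(
    r"^M(?P<idx>\d+)(_(?P<suffix>r\d|\d{2}[gl]))?$")


def preset(name: str) -> ModelConfig:
    """Expand a study-grid model name into a full configuration."""
    m = _PRESET_RE.match(name)
    if not m:
        raise ValueError(f"unknown model preset {name!r}")
    idx = int(m.group("idx"))
    suffix = m.group("suffix")
    if not 1 <= idx <= 21:
        raise ValueError(f"model index out of range in {name!r}")
    esac = -10.0 * ((idx - 1) % 7 + 1)
    cfg = ModelConfig(name=name)
    cfg.sac.e_sac_mv = esac
    if 8 <= idx <= 14:
        if not suffix or suffix[-1] not in "gl":
            raise ValueError(
                f"{name!r} needs a slowing suffix like _40g or _20l")
        cfg.fibrosis.cv_slowing = int(suffix[:-1]) / 100.0
        cfg.fibrosis.scope = ("global" if suffix[-1] == "g"
                              else "sac_region")
    elif suffix:
        if not suffix.startswith("r"):
            raise ValueError(f"radius suffix expected in {name!r}")
        cfg.geometry.sac_radius_mm = float(suffix[1:])
    if idx >= 15:
        cfg.fibrosis.clefts = True
    return cfg


@dataclass
class ModelBundle:
    """Everything a simulation run needs, built from one ModelConfig."""

    geom: object
    spec: ConductivitySpec
    het: HeterogeneityField
    clefts: object
    protocol: object
    sac: SACParams
    solver: SolverConfig
    initial_cell: object


def build_model(cfg: ModelConfig) -> ModelBundle:
    g = cfg.geometry
    geom = make_geometry(g.kind, g.dimensions_mm, g.spacing_um,
                         fiber_rotation=g.fiber_rotation,
                         endo_layer_mm=g.endo_layer_mm)
    center = (np.asarray(g.sac_center_mm) if g.sac_center_mm is not None
              else default_sac_center(geom, g.sac_transmural_frac))
    tag_sac_region(geom, center, g.sac_radius_mm, g.shell_width_mm)
    protocol = place_root_points(
        geom, layout=cfg.protocol.root_layout, bcl=cfg.protocol.bcl,
        n_prepace_beats=cfg.protocol.n_prepace_beats,
        stim_amplitude=cfg.protocol.stim_amplitude,
        stim_duration=cfg.protocol.stim_duration)
    c = cfg.conductivity
    if c.calibrate:
        spec = calibrate_conductivity(chi=c.chi, cm=c.cm,
                                      spacing_um=g.spacing_um)
    else:
        spec = ConductivitySpec(sigma_l=c.sigma_l, sigma_t=c.sigma_t,
                                endo_sigma=c.endo_sigma, chi=c.chi,
                                cm=c.cm)
    if cfg.fibrosis.cv_slowing > 0:
        spec = apply_cv_slowing(spec, cfg.fibrosis.cv_slowing,
                                cfg.fibrosis.scope, chi=c.chi, cm=c.cm,
                                spacing_um=g.spacing_um)
    het = build_iks_field(geom, cfg.cell.ab_range, cfg.cell.tm_range)
    clefts = generate_clefts(geom, cfg.seed) if cfg.fibrosis.clefts else None
    sac = SACParams(e_sac=cfg.sac.e_sac_mv, g_target_max=cfg.sac.g_target,
                    tau=cfg.sac.tau_ms, eps_switch=cfg.sac.eps_switch)
    solver = SolverConfig(
        dt_reaction=cfg.solver.dt_reaction,
        dt_diffusion=cfg.solver.dt_diffusion,
        output_interval=cfg.solver.output_interval,
        frame_interval=cfg.solver.frame_interval,
        upstroke_threshold=cfg.solver.upstroke_threshold,
        implicit=cfg.solver.implicit, use_table=cfg.solver.use_table,
        record_frames=cfg.solver.record_frames)
    cell = CellParams(variant=cfg.cell.variant,
                      iks_scale=cfg.cell.reference_iks_scale)
    initial = init_and_prepace(cell, cfg.protocol.bcl,
                               cfg.cell.n_prepace_beats)
    return ModelBundle(geom, spec, het, clefts, protocol, sac, solver,
                       initial)
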