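"""Run configuration: YAML files validated into a RunConfig.

Unknown keys are rejected everywhere.  An empty file yields the defaults:
the baseline endocardial model with control late Na+ current, paced at 1 Hz.
The ``seed`` field is reserved — every protocol here is deterministic — but
is accepted and echoed so run manifests round-trip.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .model import ModelParameters, PARAM_NAMES, SolverSettings
from . import remodeling as rm

__all__ = ["RunConfig", "load_config", "build_parameters", "build_spec",
           "build_solver_settings"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    """Overrides of named model constants, incl. the late-Na+ section."""
    constants: Dict[str, float] = {}

    @field_validator("constants")
    @classmethod
    def _known(cls, v):
        unknown = set(v) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown model constants: {sorted(unknown)}")
        return v


class OverlaySection(_Strict):
    kind: Literal["ikr_block", "ical_increase", "inal_scale", "irel_block",
                  "incx_block"]
    value: float = 0.5                 # fraction blocked / increased, or scale
    window_beats: Optional[Tuple[int, int]] = None  # transitory blocks


class RemodelingSection(_Strict):
    name: Literal["none", "hf_basic"] = "none"
    i_cab_factor: float = rm.HF_FACTORS["I_Cab"]
    i_leak_factor: float = rm.HF_FACTORS["I_leak"]
    sensitivity_parameter: Optional[str] = None
    sensitivity_mode: Optional[Literal["no_change", "double_change"]] = None
    perturb_parameters: Optional[List[str]] = None   # or ["all"]
    perturb_fraction: Optional[float] = None
    overlays: List[OverlaySection] = []


class ProtocolSection(_Strict):
    type: Literal["pace", "clamp", "staircase", "rate", "naclamp", "ead"] = "pace"
    frequency: float = 1.0
    frequencies: List[float] = [0.5, 1.0, 1.25, 1.6]
    stages: List[float] = [0.5, 1.0, 1.5, 2.0, 2.5]
    stage_minutes: float = 10.0
    beat_limit: int = 1000
    beats: int = 20                     # EAD protocol
    apd_tol: float = 0.05
    nai_tol: float = 1e-4
    record_beats: int = 2
    hold_mV: float = -120.0
    step_mV: float = -20.0
    hold_ms: float = 5000.0
    step_ms: float = 2500.0
    clamp_mM: float = 9.0               # Na clamp
    initial_snapshot: Optional[str] = None


class SolverSection(_Strict):
    rtol: float = 1e-6
    atol: float = 1e-8
    max_step: float = 1.0
    output_dt: float = 0.1
    method: str = "LSODA"


class OutputSection(_Strict):
    directory: str = "out"
    trace_format: Literal["csv", "hdf5", "both"] = "csv"


class RunConfig(_Strict):
    model: ModelSection = ModelSection()
    remodeling: RemodelingSection = RemodelingSection()
    protocol: ProtocolSection = ProtocolSection()
    solver: SolverSection = SolverSection()
    output: OutputSection = OutputSection()
    seed: int = 0


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; empty file -> all defaults."""
    text = Path(path).read_text() if path else ""
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return RunConfig(**data)


def build_parameters(cfg: RunConfig) -> ModelParameters:
    return ModelParameters().with_updates(**cfg.model.constants)


def _overlay_spec(ov: OverlaySection) -> rm.RemodelingSpec:
    if ov.kind == "ikr_block":
        return rm.ikr_block(ov.value)
    if ov.kind == "ical_increase":
        return rm.ical_increase(ov.value)
    if ov.kind == "inal_scale":
        return rm.inal_scale(ov.value)
    if ov.kind == "irel_block":
        return rm.irel_block(ov.value)
    return rm.incx_block(ov.value)


def build_spec(cfg: RunConfig):
    """(continuous spec or None, [(windowed overlay spec, (b0, b1)), ...])."""
    sec = cfg.remodeling
    spec = None
    if sec.name == "hf_basic":
        spec = rm.basic_hf_spec(sec.i_cab_factor, sec.i_leak_factor)
    if sec.sensitivity_parameter:
        if spec is None:
            raise ValueError("sensitivity variants require remodeling: hf_basic")
        spec = rm.sensitivity_variant(spec, sec.sensitivity_parameter,
                                      sec.sensitivity_mode or "no_change")
    if sec.perturb_fraction is not None:
        if spec is None:
            raise ValueError("perturbations require remodeling: hf_basic")
        pars = sec.perturb_parameters or ["all"]
        spec = rm.perturb(spec, "all" if pars == ["all"] else pars,
                          sec.perturb_fraction)
    windowed = []
    for ov in sec.overlays:
        o = _overlay_spec(ov)
        if ov.window_beats is not None:
            windowed.append((o, tuple(ov.window_beats)))
        elif spec is None:
            spec = o
        else:
            spec = rm.overlay(spec, o)
    return spec, windowed


def build_solver_settings(cfg: RunConfig) -> SolverSettings:
    s = cfg.solver
    return SolverSettings(rtol=s.rtol, atol=s.atol, max_step=s.max_step,
                          output_dt=s.output_dt, method=s.method)
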