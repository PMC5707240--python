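"""Run configuration: geometry presets, material, circulation and solver
settings, with YAML/JSON round-tripping."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .circulation import CirculationParams
from .constitutive import ActiveParams, PassiveParams
from .fibers import FiberField
from .geometry import SHAPE_PRESETS, ReferenceGeometry

__all__ = ["SolverSettings", "ModelConfig", "load_config"]


@dataclass(frozen=True)
class SolverSettings:
    """Time-stepping policy.

    dt_base : baseline step (s); dt_min : refined step used while a valve
    resistance is transitioning (s); transition_band : half-width (in units
    of 1/beta) of the pressure-difference window treated as a transition;
    newton_tol : relative tolerance of the per-stage pressure solve;
    n_cycles : number of cardiac cycles simulated.
    """

    dt_base: float = 5e-4
    dt_min: float = 5e-5
    transition_band: float = 2.5
    newton_tol: float = 1e-10
    n_cycles: int = 12
    n_mu: int = 9
    n_nu: int = 11
    n_line: int = 81
    clamp_active: bool = False

    def __post_init__(self):
        if self.dt_min > self.dt_base:
            raise ValueError("dt_min must not exceed dt_base")
        if self.n_cycles < 1:
            raise ValueError("need n_cycles >= 1")


@dataclass
class ModelConfig:
    geometry: ReferenceGeometry = field(
        default_factory=lambda: SHAPE_PRESETS["normal"])
    fibers: FiberField = field(default_factory=FiberField)
    active: ActiveParams = field(default_factory=ActiveParams)
    passive: PassiveParams = field(default_factory=PassiveParams)
    circulation: CirculationParams = field(default_factory=CirculationParams)
    solver: SolverSettings = field(default_factory=SolverSettings)
    #: initial conditions (kPa); transients decay within a few cycles
    P_A0: float = 1.5
    P_AO0: float = 10.0

    def to_dict(self):
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            d[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        return d

    def manifest(self):
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


_SECTIONS = {
    "geometry": ReferenceGeometry,
    "fibers": FiberField,
    "active": ActiveParams,
    "passive": PassiveParams,
    "circulation": CirculationParams,
    "solver": SolverSettings,
}


def load_config(path: str | Path | None = None, shape: str | None = None,
                overrides: dict | None = None) -> ModelConfig:
    """Build a ModelConfig from an optional YAML/JSON file, a named shape
    preset and/or a nested override dict.

    The fiber angles may be given in degrees with keys ``psi_in_deg`` /
    ``psi_out_deg``.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    if overrides:
        for k, v in overrides.items():
            data.setdefault(k, {}).update(v)

    cfg = ModelConfig()
    if shape is not None:
        if shape not in SHAPE_PRESETS:
            raise KeyError(f"unknown shape preset {shape!r}; "
                           f"choose from {sorted(SHAPE_PRESETS)}")
        cfg.geometry = SHAPE_PRESETS[shape]

    for name, cls in _SECTIONS.items():
        sec = dict(data.get(name, {}))
        if not sec:
            continue
        if name == "fibers":
            if "psi_in_deg" in sec:
                sec["psi_in"] = float(np.deg2rad(sec.pop("psi_in_deg")))
            if "psi_out_deg" in sec:
                sec["psi_out"] = float(np.deg2rad(sec.pop("psi_out_deg")))
        base = dataclasses.asdict(getattr(cfg, name))
        base.update(sec)
        setattr(cfg, name, cls(**base))
    for key in ("P_A0", "P_AO0"):
        if key in data:
            setattr(cfg, key, float(data[key]))
    return cfg
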