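"""Run configuration: a single YAML-serializable object gathering geometry,
femur, load, fatigue and optimizer settings, with the documented defaults.
Units are embedded in field names where they are not mm / MPa / GPa
defaults stated in the docstrings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from . import geometry as geo
from .fatigue import SNCurve
from .materials import FGMLayout, Material, builtin_catalog, default_fgm_layout
from .optimizer import OptimizerConfig
from .surrogate import LoadCase, LoadGeometry, SurrogateFemur, default_femur

__all__ = ["RunConfig", "default_config", "load_config", "save_config",
           "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    skeleton: geo.SkeletonConfig = field(default_factory=geo.SkeletonConfig)
    bounds: geo.Bounds = field(default_factory=geo.default_bounds)
    canal: tuple = field(default_factory=geo.default_canal_profile)
    femur: SurrogateFemur = field(default_factory=default_femur)
    load_case: LoadCase = field(default_factory=LoadCase)
    load_geometry: LoadGeometry = field(default_factory=LoadGeometry)
    sn_curve: SNCurve = field(default_factory=SNCurve)
    design_life: float = 2.0e6
    cement_sigma_u: float = 70.0
    stem_material: str = "ti6al4v"   # catalog name or "fgm"
    cement_material: str = "pmma"
    fgm_moduli_gpa: tuple | None = None
    thickness_limits: tuple = (2.0, 3.0)
    grid: tuple = (95, 32)
    cement_grid: tuple = (40, 16)
    ss_mode: str = "rss"
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    seed: int = 0

    def stem_material_obj(self) -> Material | FGMLayout:
        if self.stem_material == "fgm":
            if self.fgm_moduli_gpa is None:
                return default_fgm_layout(self.skeleton.total_length)
            layout = default_fgm_layout(self.skeleton.total_length)
            import numpy as np
            n = len(self.fgm_moduli_gpa)
            bounds = tuple(np.linspace(0.0, self.skeleton.total_length, n + 1))
            return FGMLayout(bounds, tuple(self.fgm_moduli_gpa))
        return builtin_catalog()[self.stem_material]


def default_config(**overrides) -> RunConfig:
    return replace(RunConfig(), **overrides) if overrides else RunConfig()


def _sanitize(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    import numpy as np
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _to_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["canal"] = [[c.a, c.b] for c in cfg.canal]
    return _sanitize(d)


def _from_dict(d: dict) -> RunConfig:
    d = dict(d)
    kw = {}
    if "skeleton" in d:
        kw["skeleton"] = geo.SkeletonConfig(**d["skeleton"])
    if "bounds" in d:
        b = d["bounds"]
        kw["bounds"] = geo.Bounds(tuple(b["lower"]), tuple(b["upper"]))
    if "canal" in d:
        kw["canal"] = tuple(geo.CanalSection(a, b) for a, b in d["canal"])
    if "femur" in d:
        kw["femur"] = SurrogateFemur(**{k: tuple(v) if isinstance(v, list) else v
                                        for k, v in d["femur"].items()
                                        if k != "bone"})
    if "load_case" in d:
        kw["load_case"] = LoadCase(**d["load_case"])
    if "load_geometry" in d:
        kw["load_geometry"] = LoadGeometry(**d["load_geometry"])
    if "sn_curve" in d:
        kw["sn_curve"] = SNCurve(**d["sn_curve"])
    if "optimizer" in d:
        kw["optimizer"] = OptimizerConfig(**d["optimizer"])
    for key in ("design_life", "cement_sigma_u", "stem_material",
                "cement_material", "seed", "ss_mode"):
        if key in d:
            kw[key] = d[key]
    for key in ("thickness_limits", "grid", "cement_grid", "fgm_moduli_gpa"):
        if key in d and d[key] is not None:
            kw[key] = tuple(d[key])
    return RunConfig(**kw)


def save_config(cfg: RunConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return _from_dict(yaml.safe_load(fh))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash identifying a configuration in output artifacts."""
    blob = json.dumps(_to_dict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
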