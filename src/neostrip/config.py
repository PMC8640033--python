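"""Pipeline configuration with YAML support.

Defaults reproduce the published operating point: LPF 3×3, mild per-slice
anisotropic diffusion, simplified bias correction, per-slice histogram
partitioning with a ±2α search window, FCM with 7 clusters / mask #2 /
ε = 0.02 / p = 2, a 3×3 disk structuring element, and eye removal with a
15 mm anterior offset, 20 mm circle model and 60th-percentile threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class LPFConfig:
    enabled: bool = True
    kernel: int = 3


@dataclass
class ADFConfig:
    enabled: bool = True
    iterations: int = 5
    kappa: float | None = None    # None -> 10% of slice 99th percentile
    lambda_: float = 0.2
    model: str = "exponential"


@dataclass
class BiasConfig:
    enabled: bool = True
    sigma_mm: float = 30.0


@dataclass
class HistConfig:
    search_window_alphas: float = 2.0
    per_slice: bool = True
    range_max: int = 255


@dataclass
class FCMConfig:
    clusters: int = 7
    mask_index: int = 2
    epsilon: float = 0.02
    fuzziness: float = 2.0
    max_iter: int = 100


@dataclass
class RefineConfig:
    connectivity: int = 8
    se: str = "disk3"


@dataclass
class EyesConfig:
    enabled: bool = True
    offset_mm: float = 15.0
    diameter_mm: float = 20.0
    percentile: float = 60.0
    accept_mm: float = 5.0
    max_eyes: int = 2


@dataclass
class PipelineConfig:
    lpf: LPFConfig = field(default_factory=LPFConfig)
    adf: ADFConfig = field(default_factory=ADFConfig)
    bias: BiasConfig = field(default_factory=BiasConfig)
    hist: HistConfig = field(default_factory=HistConfig)
    fcm: FCMConfig = field(default_factory=FCMConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    eyes: EyesConfig = field(default_factory=EyesConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        # accept the nested layout {"preprocess": {"lpf": {...}, ...}, ...}
        # as well as top-level section names
        sections = dict(d)
        pre = sections.pop("preprocess", {})
        sections = {**pre, **sections}
        for name, sub in sections.items():
            if not hasattr(cfg, name):
                raise ParameterError(f"unknown config section {name!r}")
            section = getattr(cfg, name)
            for key, val in (sub or {}).items():
                key = {"lambda": "lambda_"}.get(key, key)
                if not hasattr(section, key):
                    raise ParameterError(f"unknown config key {name}.{key}")
                setattr(section, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
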