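"""YAML run configuration: validated nested parameters with full defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .contours import ContourParams
from .features import SalientParams
from .geometry import CameraIntrinsics
from .registration import DEConfig
from .render import LightingParams
from .similarity import CostWeights


@dataclass
class RunConfig:
    salient: SalientParams = field(default_factory=SalientParams)
    contours: ContourParams = field(default_factory=ContourParams)
    weights: CostWeights = field(default_factory=CostWeights)
    de: DEConfig = field(default_factory=DEConfig)
    lighting: LightingParams = field(default_factory=LightingParams)
    intrinsics: CameraIntrinsics = field(
        default_factory=lambda: CameraIntrinsics.from_fov(90.0, 200, 200))
    length_scale: float = 2.5
    rng_seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        d = clean(asdict(self))
        d["schema"] = "pyeloreg-config/1"
        return d

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_SECTIONS = {
    "salient": SalientParams,
    "contours": ContourParams,
    "weights": CostWeights,
    "de": DEConfig,
    "lighting": LightingParams,
    "intrinsics": CameraIntrinsics,
}
_SCALARS = {"length_scale": float, "rng_seed": int, "verbosity": int}


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected and every
    sub-config's invariants are re-checked on construction."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.pop("schema", None)
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            allowed = {f.name for f in fields(cls)}
            unknown = set(value) - allowed
            if unknown:
                raise ValueError(f"unknown keys in '{key}': {sorted(unknown)}")
            def totuple(v):
                return tuple(totuple(x) for x in v) if isinstance(v, list) else v
            coerced = {k: totuple(v) for k, v in value.items()}
            try:
                kwargs[key] = cls(**coerced)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"invalid '{key}' config: {exc}") from exc
        elif key in _SCALARS:
            kwargs[key] = _SCALARS[key](value)
        else:
            raise ValueError(f"unknown config key: '{key}'")
    return RunConfig(**kwargs)
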