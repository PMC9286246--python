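"""Configuration round-tripping, dotted-path access and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
import time
from dataclasses import dataclass, field
from typing import Any

import yaml

from .model import CirculationModel, ModelError
from .substrates import SubstrateSpec


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ModelError(f"config {path} must be a mapping")
    return cfg


def _to_builtin(obj):
    """Recursively convert numpy scalars so YAML round-trips cleanly."""
    import numpy as np

    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_builtin(cfg), fh, sort_keys=True)


def get_path(cfg: dict, dotted: str) -> Any:
    """Fetch a value by dotted path, e.g. ``chambers.LV.patches.0.wall_volume``."""
    node: Any = cfg
    for part in dotted.split("."):
        if isinstance(node, list):
            node = node[int(part)]
        elif isinstance(node, dict):
            if part not in node:
                raise KeyError(f"no key {part!r} in path {dotted!r}")
            node = node[part]
        else:
            raise KeyError(f"cannot descend into {type(node).__name__} "
                           f"at {part!r} in {dotted!r}")
    return node


def set_path(cfg: dict, dotted: str, value: Any) -> None:
    parts = dotted.split(".")
    node = get_path(cfg, ".".join(parts[:-1])) if len(parts) > 1 else cfg
    last = parts[-1]
    if isinstance(node, list):
        node[int(last)] = value
    elif isinstance(node, dict):
        if last not in node:
            raise KeyError(f"no key {last!r} in path {dotted!r}")
        node[last] = value
    else:
        raise KeyError(f"cannot set {dotted!r}")


def model_to_config(model: CirculationModel) -> dict:
    return {"model": model.to_dict()}


def model_from_config(cfg: dict) -> CirculationModel:
    if "model" not in cfg:
        raise ModelError("config lacks a 'model' section")
    return CirculationModel.from_dict(cfg["model"])


def substrate_from_config(cfg: dict) -> SubstrateSpec:
    if "substrate" not in cfg:
        raise ModelError("config lacks a 'substrate' section")
    return SubstrateSpec.from_dict(cfg["substrate"])


def config_hash(cfg: dict) -> str:
    """Stable content hash (key order independent)."""
    canon = json.dumps(cfg, sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    command: str
    config_hash: str
    seed: int | None
    inputs: list[str]
    outputs: list[str]
    wall_clock_s: float = 0.0
    convergence: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.versions:
            import numpy
            import scipy

            from . import __version__

            self.versions = {
                "mrla": __version__,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "python": platform.python_version(),
            }

    def write(self, path) -> None:
        from dataclasses import asdict

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


class ManifestTimer:
    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.elapsed = time.perf_counter() - self.t0
        return False
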