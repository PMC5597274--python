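"""Run configuration: every tunable of the pipeline in one validated object."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .hier_clustering import METRICS


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunConfig:
    """All pipeline parameters with their screening-design defaults.

    The structural defaults (50 clusters, 10 representatives each, 3 arrays,
    triplicate spots, 20 homotrimer controls, alpha = 0.01) reproduce the
    focused-screen design; the noise and effect-size defaults define the
    synthetic assay conditions (log-intensity units throughout).
    """

    index_source: str = "bundled"  # "bundled" or a path to an AAindex1 file
    scale_features: bool = False
    metric: str = "euclidean"
    k_clusters: int = 50
    n_representatives: int = 10
    n_arrays: int = 3
    n_replicates: int = 3
    grid_shape: tuple[int, int] | None = None
    channels: tuple[str, ...] = ("ColIV", "ColI", "Alb")
    target_channel: str = "ColIV"
    baseline_log_intensity: float = 6.0
    sigma_array: float = 0.1
    sigma_spot: float = 0.2
    sigma_base: float = 0.5
    sigma_channel: float = 0.1
    delta_target: float = 1.0
    delta_offtarget: float = 1.0
    alpha: float = 0.01
    seed: int = 0
    output_dir: str = "results"
    extras: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if self.metric not in METRICS:
            raise ConfigError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.k_clusters < 1 or self.k_clusters > 8000:
            raise ConfigError("k_clusters must be in 1..8000")
        if self.n_representatives < 1:
            raise ConfigError("n_representatives must be >= 1")
        if self.n_arrays < 1 or self.n_replicates < 1:
            raise ConfigError("array and replicate counts must be >= 1")
        if self.target_channel not in self.channels:
            raise ConfigError(
                f"target channel {self.target_channel!r} not in {self.channels}"
            )
        if min(self.sigma_array, self.sigma_spot, self.sigma_base,
               self.sigma_channel) < 0:
            raise ConfigError("noise SDs must be non-negative")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.index_source != "bundled" and not Path(self.index_source).exists():
            raise ConfigError(f"index source file not found: {self.index_source}")
        return self

    @property
    def config_hash(self) -> str:
        payload = asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def meta(self, seed: int | None = None) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed if seed is None else seed}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "channels" in raw:
            raw["channels"] = tuple(raw["channels"])
        if raw.get("grid_shape") is not None:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw).validate()

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["channels"] = list(self.channels)
        if self.grid_shape is not None:
            payload["grid_shape"] = list(self.grid_shape)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
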