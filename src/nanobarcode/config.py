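"""Pipeline configuration: YAML round-trip, dotted overrides, run manifests.

Defaults follow the acquisition and analysis settings the workflow was
designed around: 504 x 504 px FOVs at 92.45 nm/px, a 120 nm matching radius,
an 80/20 stratified split, 10-fold cross-validation and 100 scrambling
repeats.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field, fields, replace
from datetime import datetime, timezone

import yaml

from .reader import DEFAULT_ROSTER

__all__ = ["PipelineConfig", "load_config", "write_manifest"]


@dataclass
class PipelineConfig:
    seed: int = 0
    # barcode scheme
    n_levels: int = 3
    # synthetic imaging
    particles_per_class: int = 100
    radius_mean_nm: float = 50.0
    radius_cv: float = 0.1
    encapsulation_sd: float = 1.0
    noise: bool = True
    min_separation_nm: float = 1000.0
    fov_width_px: int = 504
    fov_height_px: int = 504
    pixel_size_nm: float = 92.45
    na: float = 1.4
    # localization
    threshold_k: float = 5.0
    min_separation_px: float = 3.0
    fit_window_px: int = 7
    match_radius_nm: float = 120.0
    # reader
    test_fraction: float = 0.2
    folds: int = 10
    roster: list[str] = field(default_factory=lambda: list(DEFAULT_ROSTER))
    tuning_budget: int = 10
    scramble_repeats: int = 100
    # io
    output_dir: str = "runs"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, overrides: dict[str, str]) -> "PipelineConfig":
        """Apply flat ``key=value`` overrides, coercing to the field type."""
        out = {}
        current = self.to_dict()
        for key, raw in overrides.items():
            if key not in current:
                raise ValueError(f"unknown config key: {key}")
            out[key] = _coerce(raw, current[key])
        return replace(self, **out)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _coerce(raw, template):
    if isinstance(raw, str):
        if isinstance(template, bool):
            return raw.lower() in ("1", "true", "yes", "on")
        if isinstance(template, int) and not isinstance(template, bool):
            return int(raw)
        if isinstance(template, float):
            return float(raw)
        if isinstance(template, list):
            return [x.strip() for x in raw.split(",") if x.strip()]
    return raw


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def write_manifest(path, config: PipelineConfig, stage: str, extra: dict | None = None) -> None:
    """Record what produced an artifact directory."""
    import nanobarcode

    manifest = {
        "stage": stage,
        "config_hash": config.digest(),
        "seed": int(config.seed),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "package_version": nanobarcode.__version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
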