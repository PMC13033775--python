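"""Run configuration: YAML-backed, validated, and copied next to outputs so
every run is reproducible from its artifacts alone."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Optional, Sequence, Union

import yaml

PathLike = Union[str, Path]


@dataclass
class RunConfig:
    dataset_dir: Optional[str] = None
    output_dir: Optional[str] = None
    preset: Optional[str] = "paper_calibrated"
    arms: Optional[Sequence[str]] = None
    plan: Optional[Dict[str, Any]] = None  # inline plan parameters
    scale_r: Optional[float] = None  # mm/px; default comes from the dataset manifest
    germination_mm: float = 2.0
    energy_h: float = 72.0
    alpha: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.preset is None and self.plan is None:
            raise ValueError("config needs either a growth-model preset or inline plan")
        if self.germination_mm < 0:
            raise ValueError("germination_mm must be >= 0")
        if self.energy_h <= 0:
            raise ValueError("energy_h must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not isinstance(self.master_seed, int) or self.master_seed < 0:
            raise ValueError("master_seed must be a nonnegative integer")
        if self.scale_r is not None and self.scale_r <= 0:
            raise ValueError("scale_r must be positive")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_KNOWN_KEYS = set(RunConfig.__dataclass_fields__)


def load_config(path: PathLike) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def write_resolved_config(config: RunConfig, out_dir: PathLike, extra: Optional[dict] = None) -> Path:
    """Write the resolved config (plus hash and any extras) next to outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = asdict(config)
    payload["config_hash"] = config.config_hash()
    if extra:
        payload.update(extra)
    path = out_dir / "resolved_config.yaml"
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path
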