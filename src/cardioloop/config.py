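"""Pipeline configuration: YAML-backed, strict keys, reproducibility stamps."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    out_dir: str = "cardioloop_out"
    cohort_manifest: str | None = None      # load an existing cohort ...
    phantom: dict = field(default_factory=dict)  # ... or simulate one
    feature_preset: str = "default"
    clinical_keys: list[str] = field(default_factory=lambda: ["height_cm", "weight_kg"])
    outlier_z_threshold: float = 3.0
    misalignment_threshold: float = 0.5
    curve_jump_threshold: float = 0.08
    cv_outer_folds: int = 8
    cv_inner_folds: int = 8
    grid: dict | None = None
    importance_repeats: int = 10
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; allowed: {sorted(known)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    def echo(self, out_dir: Path) -> Path:
        """Write the resolved config next to the artifacts."""
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "resolved_config.yaml"
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def artifact_meta(config: PipelineConfig) -> dict:
    from . import __version__

    return {"config_hash": config.config_hash(), "package_version": __version__,
            "seed": config.seed}


def stamp_artifact(path: Path, config: PipelineConfig) -> None:
    """Sidecar meta file embedding (config hash, version, seed)."""
    Path(str(path) + ".meta.json").write_text(
        json.dumps(artifact_meta(config), indent=2, sort_keys=True) + "\n")
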