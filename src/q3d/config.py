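"""Pipeline configuration: every numeric parameter in one validated block.

The config is serialized verbatim (as YAML) into every output's provenance,
and its SHA-256 hash is used to refuse mixing artifacts produced under
different settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .restoration import RestorationParams
from .segmentation import DetectionParams
from .voxel_stats import TfceParams


@dataclass
class AtlasParams:
    spacing_um: float = 25.0
    roi_diameter_vox: int = 15
    roi_weights: str = "uniform"

    def validate(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError("atlas spacing must be positive")
        if self.roi_diameter_vox < 1 or self.roi_diameter_vox % 2 == 0:
            raise ValueError("ROI diameter must be odd and >= 1")
        if self.roi_weights not in ("uniform", "radial"):
            raise ValueError("roi_weights must be 'uniform' or 'radial'")


@dataclass
class StatsParams:
    alpha: float = 0.05
    tfce: TfceParams = field(default_factory=TfceParams)

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        self.tfce.validate()


@dataclass
class IoParams:
    output_dir: str = "q3d_out"
    volume_format: str = "nii"

    def validate(self) -> None:
        if self.volume_format not in ("nii", "tif"):
            raise ValueError("volume_format must be 'nii' or 'tif'")


@dataclass
class PipelineConfig:
    restoration: RestorationParams = field(default_factory=RestorationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    atlas: AtlasParams = field(default_factory=AtlasParams)
    stats: StatsParams = field(default_factory=StatsParams)
    io: IoParams = field(default_factory=IoParams)

    def validate(self) -> None:
        for section in (self.restoration, self.detection, self.atlas, self.stats, self.io):
            section.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        raw = yaml.safe_load(text) or {}
        cfg = cls(
            restoration=RestorationParams(**raw.get("restoration", {})),
            detection=DetectionParams(**raw.get("detection", {})),
            atlas=AtlasParams(**raw.get("atlas", {})),
            stats=StatsParams(
                alpha=raw.get("stats", {}).get("alpha", 0.05),
                tfce=TfceParams(**raw.get("stats", {}).get("tfce", {})),
            ),
            io=IoParams(**raw.get("io", {})),
        )
        cfg.validate()
        return cfg


__all__ = ["AtlasParams", "StatsParams", "IoParams", "PipelineConfig"]
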