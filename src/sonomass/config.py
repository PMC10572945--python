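"""Pipeline configuration: serializable, validated, defaults documented."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


def _from_mapping(cls, data: dict, path: str = ""):
    """Build a dataclass from a mapping, rejecting unknown keys by name."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        where = path or cls.__name__
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = fields[key].type
        sub = _SECTIONS.get((cls, key))
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _from_mapping(sub, value, f"{path}.{key}" if path else key)
        else:
            kwargs[key] = value
    return cls(**kwargs)


@dataclass
class PhantomConfig:
    """Synthetic-dataset stage: class-balanced phantoms."""

    n_per_class: int = 50
    height: int = 128
    width: int = 128
    speckle_shape: float = 100.0
    mass_contrast: float = 80.0


@dataclass
class AugmentConfig:
    """Expansion factor counts the original; 1 disables augmentation."""

    multiplier: int = 8
    enabled: bool = True


@dataclass
class SegmentConfig:
    ml: int = 2
    lam: float = 1.5
    k_q: int = 32
    method: str = "npoa"
    budget: int = 1500
    polarity: str = "dark"


@dataclass
class FeatureConfig:
    """``input`` selects what the curvelet transform sees: the binary ROI
    rendering (shape only), the ROI-masked image, or the raw image.
    ``normalize`` switches per-matrix unit-sum normalization; the raw
    variant keeps absolute wedge energies, which carry the cross-scale
    energy signature."""

    size: int = 128
    n_coarse_angles: int = 16
    input: str = "roi_mask"
    normalize: bool = False


@dataclass
class TrainConfig:
    s_units: int = 32
    pool: int = 2
    output: str = "softmax"
    n_polish: int = 5
    population: int = 20
    iterations: int = 30
    polish_epochs: int = 30
    batch_size: int = 12
    learning_rate: float = 1.32e-3
    c0: float = 100.0
    beta: float = 20.0
    tune: bool = False
    tune_budget: int = 24


@dataclass
class PipelineConfig:
    """Top-level configuration; a single seed determines every artifact."""

    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_mapping(cls, data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


_SECTIONS = {
    (PipelineConfig, "phantom"): PhantomConfig,
    (PipelineConfig, "augment"): AugmentConfig,
    (PipelineConfig, "segment"): SegmentConfig,
    (PipelineConfig, "features"): FeatureConfig,
    (PipelineConfig, "train"): TrainConfig,
}
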