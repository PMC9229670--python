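"""One YAML configuration drives every command.

Cross-validation requires identical hyper-parameters per fold, so a single
``RunConfig`` carries all sections (phantom, preprocess, augment, generator,
discriminator, train, eval) plus one global seed.  Unknown keys are rejected
with the offending dotted key named; an empty file yields the documented
defaults (threshold 10, closure kernel 9, lambda 75, dropout 0.1, lr 2e-4,
batch 10, 4 folds).  Sub-seeds (phantom/augment/train) are derived from the
global seed unless set explicitly, so one integer pins every stochastic
choice.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .augment import AugmentConfig
from .networks import DiscriminatorConfig, GeneratorConfig
from .phantom import PhantomConfig
from .preprocess import PreprocessConfig
from .train import TrainConfig


@dataclass
class EvalConfig:
    k: int = 4

    def validate(self) -> "EvalConfig":
        if self.k < 1:
            raise ValueError("eval.k must be >= 1")
        return self


@dataclass
class IOConfig:
    data_dir: str | None = None
    out_dir: str | None = None

    def validate(self) -> "IOConfig":
        return self


@dataclass
class RunConfig:
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    io: IOConfig = field(default_factory=IOConfig)

    def validate(self) -> "RunConfig":
        for section in dataclasses.fields(self):
            value = getattr(self, section.name)
            if hasattr(value, "validate"):
                value.validate()
        return self


_SECTIONS = {
    "phantom": PhantomConfig,
    "preprocess": PreprocessConfig,
    "augment": AugmentConfig,
    "generator": GeneratorConfig,
    "discriminator": DiscriminatorConfig,
    "train": TrainConfig,
    "eval": EvalConfig,
    "io": IOConfig,
}

# dataclass fields that are tuples (yaml hands back lists)
_TUPLE_FIELDS = {
    "radius_range", "vessel_intensity_range", "normalize_range", "zoom_range",
}


def _build_section(cls, data: dict, prefix: str):
    known = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ValueError(f"unknown configuration key: {prefix}.{key}")
        if key in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(raw: dict | None) -> RunConfig:
    raw = dict(raw or {})
    seed = raw.pop("seed", 0)
    if not isinstance(seed, int):
        raise ValueError("seed must be an integer")
    sections = {}
    for name, value in raw.items():
        if name not in _SECTIONS:
            raise ValueError(f"unknown configuration key: {name}")
        if value is None:
            value = {}
        if not isinstance(value, dict):
            raise ValueError(f"section {name} must be a mapping")
        sections[name] = _build_section(_SECTIONS[name], value, name)
    cfg = RunConfig(seed=seed, **sections)
    # one global seed pins everything not explicitly overridden
    derived = np.random.SeedSequence(seed).generate_state(3)
    if "seed" not in (raw.get("phantom") or {}):
        cfg.phantom.seed = int(derived[0]) % (2**31)
    if "seed" not in (raw.get("augment") or {}):
        cfg.augment.seed = int(derived[1]) % (2**31)
    if "seed" not in (raw.get("train") or {}):
        cfg.train.seed = int(derived[2]) % (2**31)
    return cfg.validate()


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration (empty file = defaults)."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is not None and not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    payload = dataclasses.asdict(cfg)
    for name in _TUPLE_FIELDS:
        for section in payload.values():
            if isinstance(section, dict) and name in section:
                section[name] = list(section[name])
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
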