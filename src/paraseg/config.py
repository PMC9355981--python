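"""Declarative run configuration (YAML) for the end-to-end experiment.

A run config nests the per-module configs plus a cohort description, a
split rule and the list of model cells (dims x augmentation, optional
deeper variant) to train and compare. Unknown keys are rejected so typos
fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import yaml

from .augment import AugmentConfig
from .nn import UNetConfig
from .phantom import PhantomConfig
from .train import TrainConfig


@dataclass
class CohortConfig:
    n: int = 24

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("cohort needs at least 2 subjects")


@dataclass
class SplitConfig:
    mode: str = "holdout"  # "holdout" or "kfold"
    n_train: int = 16      # holdout only
    k: int = 3             # kfold only

    def __post_init__(self):
        if self.mode not in ("holdout", "kfold"):
            raise ValueError(f"split mode must be 'holdout' or 'kfold', got {self.mode!r}")


@dataclass
class CellConfig:
    """One model cell of the comparison (e.g. 2D without augmentation)."""
    dims: int = 2
    augment: bool = False
    deeper: bool = False

    @property
    def name(self) -> str:
        return (f"{self.dims}d" + ("_aug" if self.augment else "_noaug")
                + ("_deeper" if self.deeper else ""))


@dataclass
class NetworkConfig:
    channels: tuple = (16, 32, 64, 128, 256)
    negative_slope: float = 0.01
    out_channels: int = 7


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    cells: list = field(default_factory=lambda: [CellConfig()])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cells"] = [asdict(c) if isinstance(c, CellConfig) else c for c in self.cells]
        return d


_BLOCKS = {"phantom": PhantomConfig, "cohort": CohortConfig, "split": SplitConfig,
           "augment": AugmentConfig, "network": NetworkConfig, "train": TrainConfig}


def _build(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in '{context}' block")
    data = {k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()}
    return cls(**data)


def run_config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw or {})
    kwargs = {}
    for name, cls in _BLOCKS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw.pop(name) or {}, name)
    if "cells" in raw:
        kwargs["cells"] = [_build(CellConfig, c, "cells") for c in raw.pop("cells")]
    for key in ("seed", "out_dir"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ValueError(f"unknown top-level config keys {sorted(raw)}")
    return RunConfig(**kwargs)


def load_run_config(path: str) -> RunConfig:
    with open(path) as fh:
        return run_config_from_dict(yaml.safe_load(fh))
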