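"""Pipeline configuration: one validated block per stage.

Defaults encode the procedural constants of the analysis: 10 contiguous
encoding folds, a significance gate at p = 0.001, top-100 contrast corpora,
3 discovery folds, 10,000 permutations for the channel test, FDR at 0.05,
19-word context and 25 ms bins (20 bins over 0-500 ms) in the simulator.
A minimal config needs only ``seed``; unknown keys anywhere are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .encoding import DEFAULT_LAMBDA_GRID
from .simulate import SimConfig


@dataclass
class EncodingConfig:
    folds: int = 10
    inner_folds: int = 5
    lambda_grid: list = field(default_factory=lambda: list(DEFAULT_LAMBDA_GRID))
    per_channel_lambda: bool = False
    n_layers: int = 3
    enabled: bool = True

    def validate(self) -> None:
        if self.folds < 2:
            raise ValueError("encoding.folds must be >= 2")
        if self.inner_folds < 2:
            raise ValueError("encoding.inner_folds must be >= 2")
        if not self.lambda_grid or any(l < 0 for l in self.lambda_grid):
            raise ValueError("encoding.lambda_grid must be non-empty, values >= 0")
        if self.n_layers < 1:
            raise ValueError("encoding.n_layers must be >= 1")


@dataclass
class DivergenceConfig:
    alpha: float = 0.001
    top_n: int = 100
    pool: str = "cells"
    enabled: bool = True

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("divergence.alpha must be in (0, 1)")
        if self.top_n < 1:
            raise ValueError("divergence.top_n must be >= 1")
        if self.pool not in ("cells", "channels"):
            raise ValueError("divergence.pool must be 'cells' or 'channels'")


@dataclass
class DiscoveryConfig:
    folds: int = 3
    n_hypotheses: int = 10
    n_perm: int = 1000
    proposer: str = "mock"
    verifier: str = "mock"
    enabled: bool = True

    def validate(self) -> None:
        if self.folds < 1:
            raise ValueError("discovery.folds must be >= 1")
        if self.n_perm < 1:
            raise ValueError("discovery.n_perm must be >= 1")
        if self.proposer != "mock" or self.verifier != "mock":
            raise ValueError("only the 'mock' backends ship with the package")


@dataclass
class MCConfig:
    n_items: int = 300
    n_options: int = 3
    epochs: int = 30
    lr: float = 0.5
    holdout_fraction: float = 0.25
    use_log_softmax: bool = False
    enabled: bool = True

    def validate(self) -> None:
        if self.n_options < 2:
            raise ValueError("mc.n_options must be >= 2")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("mc.holdout_fraction must be in (0, 1)")
        if self.epochs < 0:
            raise ValueError("mc.epochs must be >= 0")


@dataclass
class ComparisonConfig:
    n_perm: int = 10000
    alpha: float = 0.05
    category: str = "planted"
    lm_folds: int = 3
    lm_epochs: int = 40
    enabled: bool = True

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("comparison.n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("comparison.alpha must be in (0, 1)")
        if self.lm_folds < 2:
            raise ValueError("comparison.lm_folds must be >= 2")


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str = "pipeline_out"
    sim: SimConfig = None  # type: ignore[assignment]
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    divergence: DivergenceConfig = field(default_factory=DivergenceConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    mc: MCConfig = field(default_factory=MCConfig)
    comparison: ComparisonConfig = field(default_factory=ComparisonConfig)

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)

    def validate(self) -> None:
        """Check every stage block before any stage runs."""
        for block in (self.encoding, self.divergence, self.discovery,
                      self.mc, self.comparison):
            block.validate()
        if self.encoding.folds > self.sim.n_words:
            raise ValueError("encoding.folds exceeds sim.n_words")

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "sim": self.sim.to_dict(),
        }
        for name in ("encoding", "divergence", "discovery", "mc", "comparison"):
            d[name] = dataclasses.asdict(getattr(self, name))
        return d

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


_BLOCKS = {
    "encoding": EncodingConfig,
    "divergence": DivergenceConfig,
    "discovery": DiscoveryConfig,
    "mc": MCConfig,
    "comparison": ComparisonConfig,
}


def _build(cls, data: dict, prefix: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {prefix}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    if "seed" not in data:
        raise ValueError("missing required field: seed")
    top_allowed = {"seed", "out_dir", "sim"} | set(_BLOCKS)
    unknown = set(data) - top_allowed
    if unknown:
        raise ValueError(f"unknown key(s) in config: {sorted(unknown)}")
    seed = data.pop("seed")
    out_dir = data.pop("out_dir", "pipeline_out")
    sim_block = dict(data.pop("sim", {}))
    sim_block.setdefault("seed", seed)
    sim = _build(SimConfig, sim_block, "sim")
    kwargs = {}
    for name, cls in _BLOCKS.items():
        kwargs[name] = _build(cls, dict(data.pop(name, {})), name)
    cfg = PipelineConfig(seed=seed, out_dir=out_dir, sim=sim, **kwargs)
    cfg.validate()
    return cfg


def load_config(path) -> PipelineConfig:
    """Load and fully validate a YAML (or JSON, a YAML subset) config."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    return config_from_dict(data)
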