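"""Run configuration: one validated YAML document covering every stage.

Unknown keys are rejected so typos fail at startup, and every pipeline
run writes the fully-resolved configuration next to its outputs for
reproducibility.
"""

from __future__ import annotations

import logging

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .aggregation import AggregateConfig
from .dl_model import AugmentParams, NetConfig
from .expert_system import ExpertTreeConfig
from .gait_events import GaitConfig
from .indicators import IndicatorConfig
from .ml_models import ModelSpec

logger = logging.getLogger("bovigait")

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class IOSection(_Strict):
    max_gap: int = 3
    format: str = "coco_json"


class GaitSection(_Strict):
    speed_frac: float = 0.15
    min_run: int = 3
    initial_phase_frac: float = 0.2

    def to_dataclass(self) -> GaitConfig:
        return GaitConfig(**self.model_dump())


class IndicatorSection(_Strict):
    angle_mode: str = "projected"
    height_mode: str = "anatomical"
    leg_window: int = 10

    def to_dataclass(self) -> IndicatorConfig:
        return IndicatorConfig(**self.model_dump())


class AggregateSection(_Strict):
    window: int = 5
    spine_blend: float = 0.5
    initial_phase_frac: float = 0.2

    def to_dataclass(self) -> AggregateConfig:
        return AggregateConfig(**self.model_dump())


class ExpertSection(_Strict):
    """Expert-tree thresholds; left unset, they are calibrated from the
    labeled features of the run itself."""

    theta_head_7: float | None = None
    theta_spine_12_36: float | None = None
    theta_spine_1_2: float | None = None
    theta_legs_3_46: float | None = None
    theta_head_45_6: float | None = None
    merged_45_output: float = 4.5

    def to_dataclass(self) -> ExpertTreeConfig | None:
        vals = self.model_dump()
        merged = vals.pop("merged_45_output")
        if any(v is None for v in vals.values()):
            return None
        return ExpertTreeConfig(merged_45_output=merged, **vals)


class MLSection(_Strict):
    family: str = "random_forest"
    task: str = "grade7"
    hyperparameters: dict = Field(default_factory=dict)

    def to_spec(self, seed: int) -> ModelSpec:
        return ModelSpec(family=self.family, task=self.task,
                         hyperparameters=dict(self.hyperparameters), seed=seed)


class DLSection(_Strict):
    sequence_length: int = 120
    conv_filters: tuple[int, ...] = (128, 192, 320)
    learning_rate: float = 1e-3
    dropout: float = 0.1
    epochs: int = 30
    batch_size: int = 16
    augment_noise_sigma: float = 0.01
    augment_smooth_window: int = 0
    augment_dropout_frac: float = 0.1
    n_augment: int = 0  # extra augmented copies per training sample
    model_path: str | None = None

    def to_net_config(self, seed: int) -> NetConfig:
        return NetConfig(conv_filters=tuple(self.conv_filters),
                         learning_rate=self.learning_rate, dropout=self.dropout,
                         epochs=self.epochs, batch_size=self.batch_size, seed=seed)

    def to_augment_params(self) -> AugmentParams:
        return AugmentParams(noise_sigma=self.augment_noise_sigma,
                             smooth_window=self.augment_smooth_window,
                             dropout_frac=self.augment_dropout_frac)


class RunConfig(_Strict):
    io: IOSection = Field(default_factory=IOSection)
    gait: GaitSection = Field(default_factory=GaitSection)
    indicators: IndicatorSection = Field(default_factory=IndicatorSection)
    aggregate: AggregateSection = Field(default_factory=AggregateSection)
    expert: ExpertSection = Field(default_factory=ExpertSection)
    ml: MLSection = Field(default_factory=MLSection)
    dl: DLSection = Field(default_factory=DLSection)
    seed: int = 0
    log_level: str = "INFO"


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML run configuration (defaults when None)."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return RunConfig(**doc)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
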