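"""Experiment configuration: YAML loading and reproducible seed fan-out."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .core import ValidationError
from .models import SeqModelConfig
from .synthetic import EmitterConfig, WorkflowSimConfig
from .training import TrainConfig

__all__ = ["ExperimentConfig", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed and stage name.

    Stages are thereby independently reproducible: re-running a single stage
    with the same global seed regenerates exactly the same stream.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


@dataclass
class ExperimentConfig:
    seed: int = 0
    n_train: int = 8
    n_val: int = 2
    n_test: int = 2
    segment_mode: str = "sync"  # sync | shifted | modeavg
    mode_filter_width: int = 101
    sim: WorkflowSimConfig = field(default_factory=WorkflowSimConfig)
    emitter: EmitterConfig = field(default_factory=EmitterConfig)
    model: SeqModelConfig = field(default_factory=SeqModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def validate(self) -> None:
        if min(self.n_train, self.n_test) < 1 or self.n_val < 0:
            raise ValidationError("need >= 1 training and test video")
        if self.segment_mode not in ("sync", "shifted", "modeavg"):
            raise ValidationError(f"unknown segment_mode {self.segment_mode!r}")
        if self.mode_filter_width < 1 or self.mode_filter_width % 2 == 0:
            raise ValidationError("mode_filter_width must be odd and >= 1")
        self.sim.validate()
        self.emitter.validate()
        self.model.validate()
        self.train.validate()

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        def build(klass, key):
            section = dict(raw.get(key) or {})
            for tuple_key in ("phase_mean_s", "phase_sd_s", "transition_range_s",
                              "pause_range_s", "lead_range_s"):
                if tuple_key in section and isinstance(section[tuple_key], list):
                    section[tuple_key] = tuple(section[tuple_key])
            try:
                return klass(**section)
            except TypeError as exc:
                raise ValidationError(f"bad {key} section: {exc}") from exc

        top = {k: v for k, v in raw.items()
               if k in ("seed", "n_train", "n_val", "n_test", "segment_mode",
                        "mode_filter_width")}
        cfg = cls(sim=build(WorkflowSimConfig, "sim"),
                  emitter=build(EmitterConfig, "emitter"),
                  model=build(SeqModelConfig, "model"),
                  train=build(TrainConfig, "train"), **top)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
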