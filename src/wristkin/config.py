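"""Validated pipeline configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignBlock(_Strict):
    n_subjects: int = 5
    objects: list[str] = ["cylinder", "sphere"]
    slots: list[str] = ["DL", "DR", "UL", "UR"]
    n_repetitions: int = 3
    rate_hz: float = 60.0
    duration_s: float = 5.0
    pos_noise_cm: float = 0.1
    angle_noise_deg: float = 0.5
    timing_jitter: float = 0.1


class FilterBlock(_Strict):
    cutoff_hz: float = 5.0
    zero_phase: bool = True


class DtwBlock(_Strict):
    channel_set: str = "hand_position"  # or "angles"

    @field_validator("channel_set")
    @classmethod
    def _known(cls, v):
        if v not in ("hand_position", "angles"):
            raise ValueError("dtw.channel_set must be hand_position or angles")
        return v


class TaperBlock(_Strict):
    len: int = 5


class EventsBlock(_Strict):
    anticipations_s: list[float] = [0.5, 0.75]
    segmentation: str = "halves"  # or "local_minima"


class ModelBlock(_Strict):
    neurons: list[int] = [5, 10, 15, 20]
    delay_specs: list[str] = ["1:10", "1:15", "1:2", "11:12"]
    trainers: list[str] = ["bayes-lm"]
    extensions: list[str] = []
    sessions: int = 5
    test_fraction: float = 0.15
    ffnn_max_epochs: int = 100
    tdnn_max_epochs: int = 30


class PipelineConfig(_Strict):
    """Everything a full pipeline run needs, in one validated object."""

    design: DesignBlock = Field(default_factory=DesignBlock)
    filter: FilterBlock = Field(default_factory=FilterBlock)
    dtw: DtwBlock = Field(default_factory=DtwBlock)
    taper: TaperBlock = Field(default_factory=TaperBlock)
    events: EventsBlock = Field(default_factory=EventsBlock)
    model: ModelBlock = Field(default_factory=ModelBlock)
    study_seed: int = 42
    experiment_seed: int = 1
    outdir: str = "wristkin_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    def study_design(self):
        from .synthetic import StudyDesign

        d = self.design
        return StudyDesign(
            n_subjects=d.n_subjects, objects=tuple(d.objects),
            slots=tuple(d.slots), n_repetitions=d.n_repetitions,
            rate_hz=d.rate_hz, duration_s=d.duration_s,
            pos_noise_cm=d.pos_noise_cm, angle_noise_deg=d.angle_noise_deg,
            timing_jitter=d.timing_jitter,
        )
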