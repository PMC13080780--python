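"""Run configuration: defaults, YAML/JSON round-trip and validation.

Every threshold with a stated protocol value defaults to it: 2 s ISI,
0.5 s stimuli, 240 s task between two 10 s baselines, 7–21 standards
between targets, 30 kΩ impedance limit, SCI 0.4, 0–45 Hz EEG band,
0.08 Hz fNIRS low-pass, [−0.2, 1] s ERP epochs with a [250, 400] ms P300
window, [−1, 20] s HbO epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .synthetic_participant import (CohortDistribution, NoiseModel,
                                    ParticipantProfile)
from .task_engine import TaskConfig


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass(frozen=True)
class PipelineConfig:
    impedance_max_kohm: float = 30.0
    sci_min: float = 0.4
    eeg_lowpass_hz: float = 45.0
    eeg_line_freq_hz: float = 60.0
    eeg_artifact_uv: float = 100.0
    eeg_epoch_window_s: tuple[float, float] = (-0.2, 1.0)
    p300_window_ms: tuple[float, float] = (250.0, 400.0)
    fnirs_lowpass_hz: float = 0.08
    hbo_epoch_window_s: tuple[float, float] = (-1.0, 20.0)
    response_floor_ms: float = 100.0
    participant_exclusion_fraction: float = 0.5
    wilcoxon_continuity: bool = False
    i0_mode: str = "mean"

    def validate(self) -> None:
        checks = [
            ("impedance_max_kohm", self.impedance_max_kohm > 0),
            ("sci_min", 0.0 <= self.sci_min <= 1.0),
            ("eeg_lowpass_hz", self.eeg_lowpass_hz > 0),
            ("fnirs_lowpass_hz", self.fnirs_lowpass_hz > 0),
            ("eeg_epoch_window_s",
             self.eeg_epoch_window_s[0] < 0 < self.eeg_epoch_window_s[1]),
            ("p300_window_ms",
             0 <= self.p300_window_ms[0] < self.p300_window_ms[1]),
            ("hbo_epoch_window_s",
             self.hbo_epoch_window_s[0] < 0 < self.hbo_epoch_window_s[1]),
            ("response_floor_ms", self.response_floor_ms >= 0),
            ("participant_exclusion_fraction",
             0.0 < self.participant_exclusion_fraction <= 1.0),
            ("i0_mode", self.i0_mode in ("mean", "first_baseline")),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigError(
                    f"pipeline.{name}: value {getattr(self, name)!r} "
                    f"violates its constraint")


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 53
    distribution: CohortDistribution = field(
        default_factory=CohortDistribution)
    eeg_rate: float = 250.0
    fnirs_rate: float = 10.0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("cohort.n_participants: must be >= 1")
        if self.eeg_rate <= 90:
            raise ConfigError("cohort.eeg_rate: must be > 90 Hz for the "
                              "45 Hz passband")
        if self.fnirs_rate <= 0.16:
            raise ConfigError("cohort.fnirs_rate: must be > 0.16 Hz")


@dataclass(frozen=True)
class RunConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    profile: ParticipantProfile = field(default_factory=ParticipantProfile)
    noise: NoiseModel = field(default_factory=NoiseModel)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 1
    output: str = "pocketlab_out"

    def validate(self) -> "RunConfig":
        self.pipeline.validate()
        self.cohort.validate()
        try:
            self.noise.check_rates(self.cohort.eeg_rate,
                                   self.cohort.fnirs_rate)
        except ValueError as e:
            raise ConfigError(f"noise: {e}") from e
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def default_config() -> RunConfig:
    return RunConfig()


def _tupleize(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if k.endswith(("_window_s", "_window_ms")) and isinstance(v, list):
            v = tuple(v)
        out[k] = v
    return out


def config_from_dict(d: dict) -> RunConfig:
    try:
        kwargs: dict = {}
        if "task" in d:
            kwargs["task"] = TaskConfig(**d["task"])
        if "cohort" in d:
            c = dict(d["cohort"])
            if "distribution" in c:
                c["distribution"] = CohortDistribution(**c["distribution"])
            kwargs["cohort"] = CohortConfig(**c)
        if "profile" in d:
            kwargs["profile"] = ParticipantProfile(**d["profile"])
        if "noise" in d:
            kwargs["noise"] = NoiseModel(**d["noise"])
        if "pipeline" in d:
            kwargs["pipeline"] = PipelineConfig(**_tupleize(d["pipeline"]))
        for k in ("seed", "output"):
            if k in d:
                kwargs[k] = d[k]
        unknown = set(d) - {"task", "cohort", "profile", "noise",
                            "pipeline", "seed", "output"}
        if unknown:
            raise ConfigError(f"unknown config field(s): "
                              f"{', '.join(sorted(unknown))}")
        return RunConfig(**kwargs).validate()
    except TypeError as e:
        raise ConfigError(str(e)) from e
    except ValueError as e:
        if isinstance(e, ConfigError):
            raise
        raise ConfigError(str(e)) from e


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration; omitted fields default."""
    path = Path(path)
    text = path.read_text()
    d = (json.loads(text) if path.suffix == ".json"
         else yaml.safe_load(text)) or {}
    if not isinstance(d, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(d)


def dump_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=1))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
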