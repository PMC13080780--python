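"""Oddball stimulus scheduling and task-event streams.

The visual oddball task presents a frequent "standard" stimulus and an
infrequent "target" stimulus at a fixed onset-to-onset interval (ISI).
Targets are separated by a bounded number of standards so that their
appearance stays unpredictable. A run is bracketed by two silent baseline
periods. Every task event is mirrored into three record streams —
``metadata`` (configuration and run phase markers), ``stimulus`` (one record
per presentation) and ``marker`` (participant button presses) — matching the
three outlets a mobile task platform publishes to a lab-streaming recorder.

All timestamps are seconds on a run-local monotonic clock that reads 0 at
the moment the run begins (start of the first baseline).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

TARGET = "target"
STANDARD = "standard"

STREAM_METADATA = "metadata"
STREAM_STIMULUS = "stimulus"
STREAM_MARKER = "marker"


class ScheduleError(ValueError):
    """Raised when a task configuration cannot produce a valid schedule."""


@dataclass(frozen=True)
class TaskConfig:
    """Timing and sequencing parameters of one oddball run.

    Parameters
    ----------
    isi
        Onset-to-onset interstimulus interval, seconds.
    stim_duration
        On-screen duration of each stimulus, seconds (must be < ``isi``).
    task_duration
        Length of the stimulation block, seconds.
    baseline_duration
        Silent rest period before and after the stimulation block, seconds.
    gap_min, gap_max
        Inclusive bounds on the number of standard stimuli between two
        consecutive targets.
    clock_offset, clock_jitter_sd
        Optional constant offset (s) and per-record Gaussian jitter (s)
        applied to emitted stream timestamps, for robustness testing of
        downstream consumers. Both default to 0 (ideal monotonic clock).
    """

    isi: float = 2.0
    stim_duration: float = 0.5
    task_duration: float = 240.0
    baseline_duration: float = 10.0
    gap_min: int = 7
    gap_max: int = 21
    seed: int = 0
    clock_offset: float = 0.0
    clock_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.isi > 0 and self.task_duration > 0
                and self.baseline_duration > 0 and self.stim_duration > 0):
            raise ValueError("all durations must be > 0")
        if not self.stim_duration < self.isi:
            raise ValueError("stim_duration must be < isi")
        if self.gap_min < 1:
            raise ValueError("gap_min must be >= 1")
        if self.gap_min > self.gap_max:
            raise ValueError("gap_min must be <= gap_max")

    @property
    def n_events(self) -> int:
        return int(np.floor(self.task_duration / self.isi))

    @property
    def run_duration(self) -> float:
        """Total run length: baseline + task + baseline, seconds."""
        return 2 * self.baseline_duration + self.task_duration

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        return cls(**d)


@dataclass(frozen=True)
class StimulusEvent:
    onset: float            # seconds from run start
    stimulus_class: str     # TARGET or STANDARD
    index: int              # ordinal within the run


@dataclass(frozen=True)
class StimulusSchedule:
    config: TaskConfig
    events: tuple[StimulusEvent, ...]

    @property
    def target_indices(self) -> list[int]:
        return [e.index for e in self.events if e.stimulus_class == TARGET]

    def gaps(self) -> list[int]:
        """Counts of standards strictly between consecutive targets."""
        ti = self.target_indices
        return [b - a - 1 for a, b in zip(ti, ti[1:])]


@dataclass(frozen=True)
class EventRecord:
    stream: str
    timestamp: float
    payload: str  # "key=value" pairs joined by ';'

    def fields(self) -> dict[str, str]:
        out = {}
        for part in self.payload.split(";"):
            if "=" in part:
                k, v = part.split("=", 1)
                out[k] = v
        return out


@dataclass
class EventStreamSet:
    metadata: list[EventRecord] = field(default_factory=list)
    stimulus: list[EventRecord] = field(default_factory=list)
    marker: list[EventRecord] = field(default_factory=list)

    def all_records(self) -> list[EventRecord]:
        return [*self.metadata, *self.stimulus, *self.marker]


def generate_oddball_schedule(config: TaskConfig,
                              rng: np.random.Generator | None = None
                              ) -> StimulusSchedule:
    """Generate one oddball run satisfying the gap constraints.

    Gap lengths (standards between consecutive targets, and before the first
    target) are drawn independently and uniformly over the integers
    ``[gap_min, gap_max]``. The sequence is truncated at ``n_events``, so the
    final stretch after the last target may hold fewer than ``gap_min``
    standards. Deterministic given ``config.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_events
    if n < config.gap_min + 1:
        raise ScheduleError(
            f"task too short for one target: {n} events < gap_min"
            f"+1 = {config.gap_min + 1}")
    classes: list[str] = []
    while len(classes) < n:
        gap = int(rng.integers(config.gap_min, config.gap_max + 1))
        classes.extend([STANDARD] * gap)
        classes.append(TARGET)
    classes = classes[:n]
    events = tuple(
        StimulusEvent(onset=config.baseline_duration + i * config.isi,
                      stimulus_class=c, index=i)
        for i, c in enumerate(classes))
    return StimulusSchedule(config=config, events=events)


def validate_schedule(schedule: StimulusSchedule) -> list[dict]:
    """Check every schedule invariant; return one report entry per violation.

    An empty list means the schedule is valid. Each entry carries
    ``invariant``, a human-readable ``detail`` and the offending ``indices``.
    """
    cfg = schedule.config
    ev = schedule.events
    report: list[dict] = []

    def fail(invariant: str, detail: str, indices: list[int]) -> None:
        report.append({"invariant": invariant, "detail": detail,
                       "indices": indices})

    if len(ev) != cfg.n_events:
        fail("event_count",
             f"expected floor(task_duration/isi) = {cfg.n_events} events, "
             f"got {len(ev)}", [])
    if ev and abs(ev[0].onset - cfg.baseline_duration) > 1e-9:
        fail("first_onset",
             f"first onset {ev[0].onset} != baseline_duration "
             f"{cfg.baseline_duration}", [0])
    bad_steps = [b.index for a, b in zip(ev, ev[1:])
                 if abs((b.onset - a.onset) - cfg.isi) > 1e-9]
    if bad_steps:
        fail("onset_spacing",
             f"consecutive onsets must differ by isi = {cfg.isi} s",
             bad_steps)
    nonmono = [b.index for a, b in zip(ev, ev[1:]) if b.onset <= a.onset]
    if nonmono:
        fail("onsets_increasing", "onsets must strictly increase", nonmono)
    ti = schedule.target_indices
    for a, b in zip(ti, ti[1:]):
        gap = b - a - 1
        if gap < cfg.gap_min:
            fail("gap_min", f"only {gap} standards before target at index "
                 f"{b} (min {cfg.gap_min})", [b])
        elif gap > cfg.gap_max:
            fail("gap_max", f"{gap} standards before target at index {b} "
                 f"(max {cfg.gap_max})", [b])
    return report


def _rec(stream: str, t: float, cfg: TaskConfig,
         rng: np.random.Generator | None, **kv) -> EventRecord:
    if cfg.clock_jitter_sd > 0 and rng is not None:
        t = t + rng.normal(0.0, cfg.clock_jitter_sd)
    payload = ";".join(f"{k}={v}" for k, v in kv.items())
    return EventRecord(stream=stream, timestamp=t + cfg.clock_offset,
                       payload=payload)


def schedule_to_event_streams(schedule: StimulusSchedule) -> EventStreamSet:
    """Serialize a schedule as the three task-event streams.

    The metadata stream opens with the full config serialization (audit
    record), then carries baseline/task start and stop phase markers. The
    stimulus stream holds one record per presentation with its class and
    onset. The marker stream is empty until responses are simulated or
    recorded.
    """
    cfg = schedule.config
    rng = (np.random.default_rng(cfg.seed + 1)
           if cfg.clock_jitter_sd > 0 else None)
    streams = EventStreamSet()
    t_task_start = cfg.baseline_duration
    t_task_stop = cfg.baseline_duration + cfg.task_duration
    t_run_stop = t_task_stop + cfg.baseline_duration
    streams.metadata.append(
        _rec(STREAM_METADATA, 0.0, cfg, rng, event="config",
             config=json.dumps(cfg.to_dict(), sort_keys=True)))
    streams.metadata.append(
        _rec(STREAM_METADATA, 0.0, cfg, rng, event="baseline_start"))
    streams.metadata.append(
        _rec(STREAM_METADATA, t_task_start, cfg, rng, event="baseline_stop"))
    streams.metadata.append(
        _rec(STREAM_METADATA, t_task_start, cfg, rng, event="task_start"))
    for e in schedule.events:
        streams.stimulus.append(
            _rec(STREAM_STIMULUS, e.onset, cfg, rng,
                 stimulus_class=e.stimulus_class, onset=repr(e.onset),
                 index=e.index))
    streams.metadata.append(
        _rec(STREAM_METADATA, t_task_stop, cfg, rng, event="task_stop"))
    streams.metadata.append(
        _rec(STREAM_METADATA, t_task_stop, cfg, rng, event="baseline_start"))
    streams.metadata.append(
        _rec(STREAM_METADATA, t_run_stop, cfg, rng, event="baseline_stop"))
    return streams


# ---------------------------------------------------------------------------
# JSON-lines interchange

def write_event_streams(streams: EventStreamSet, path: str | Path) -> None:
    """Write all records as JSON-lines (stream/timestamp/payload per line)."""
    records = sorted(streams.all_records(),
                     key=lambda r: (r.timestamp,
                                    [STREAM_METADATA, STREAM_STIMULUS,
                                     STREAM_MARKER].index(r.stream)))
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps({"stream": r.stream,
                                 "timestamp": r.timestamp,
                                 "payload": r.payload}) + "\n")


def read_event_streams(path: str | Path) -> EventStreamSet:
    streams = EventStreamSet()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            rec = EventRecord(stream=d["stream"], timestamp=d["timestamp"],
                              payload=d["payload"])
            getattr(streams, rec.stream).append(rec)
    return streams


def stimulus_events_from_streams(streams: EventStreamSet
                                 ) -> list[StimulusEvent]:
    """Recover the stimulus event list from a stream set."""
    out = []
    for r in streams.stimulus:
        f = r.fields()
        out.append(StimulusEvent(onset=float(f["onset"]),
                                 stimulus_class=f["stimulus_class"],
                                 index=int(f["index"])))
    return sorted(out, key=lambda e: e.index)


def config_from_streams(streams: EventStreamSet) -> TaskConfig:
    for r in streams.metadata:
        f = r.fields()
        if f.get("event") == "config":
            return TaskConfig.from_dict(json.loads(f["config"]))
    raise ValueError("metadata stream carries no config record")
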