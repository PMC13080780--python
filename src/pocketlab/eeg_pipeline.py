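"""EEG preprocessing, stimulus-locked epoching and P300 extraction.

Channels with electrode impedance above 30 kΩ are pruned. The continuous
recording is band-limited to 0–45 Hz with a zero-phase low-pass (so peak
latencies are unbiased) plus a zero-phase notch at the power-line
frequency; samples exceeding an amplitude threshold (default ±100 µV) are
marked and any epoch containing a marked sample on a valid channel is
rejected. Epochs span −0.2 to +1.0 s around stimulus onset and are
baseline-corrected by subtracting the prestimulus mean. Class-wise trial
averages give the event-related potential (ERP); the P300 is read out as
the maximum of the class-mean waveform in a 250–400 ms window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .synthetic_participant import RawEEG
from .task_engine import StimulusEvent

logger = logging.getLogger(__name__)

IMPEDANCE_MAX_KOHM = 30.0
EEG_LOWPASS_HZ = 45.0
ARTIFACT_THRESHOLD_UV = 100.0
EPOCH_WINDOW_S = (-0.2, 1.0)
P300_WINDOW_MS = (250.0, 400.0)


@dataclass
class ChannelMask:
    valid: np.ndarray              # bool per channel
    reasons: list[str | None]      # None for valid channels

    def __len__(self) -> int:
        return len(self.valid)

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())


@dataclass
class Epochs:
    data: np.ndarray               # trials x channels x samples, µV
    times: np.ndarray              # s relative to stimulus onset
    classes: list[str]             # per trial
    labels: list[str]
    rate: float
    baseline_corrected: bool = False
    n_rejected: int = 0
    n_dropped_edge: int = 0


@dataclass
class ERPResult:
    stimulus_class: str
    mean: np.ndarray               # channels x samples
    sem: np.ndarray                # channels x samples
    times: np.ndarray
    labels: list[str]
    n_trials: int


@dataclass(frozen=True)
class P300Peak:
    latency_ms: float
    amplitude_uv: float
    positive: bool                 # False flags "no positive peak"


def validate_channels_eeg(impedances,
                          threshold_kohm: float = IMPEDANCE_MAX_KOHM
                          ) -> ChannelMask:
    """Mark channels invalid iff impedance strictly exceeds the threshold."""
    imp = np.asarray(impedances, dtype=float)
    if not np.all(np.isfinite(imp)) or np.any(imp < 0):
        raise ValueError("impedances must be finite and nonnegative")
    valid = imp <= threshold_kohm
    reasons = [None if v else f"impedance {i:.1f} kΩ > {threshold_kohm:g} kΩ"
               for v, i in zip(valid, imp)]
    return ChannelMask(valid=valid, reasons=reasons)


def preprocess_eeg(raw: RawEEG,
                   lowpass_hz: float = EEG_LOWPASS_HZ,
                   line_freq: float = 60.0,
                   artifact_threshold_uv: float = ARTIFACT_THRESHOLD_UV,
                   ) -> tuple[RawEEG, np.ndarray]:
    """Zero-phase 0–45 Hz low-pass + line notch; mark amplitude artifacts.

    Returns the filtered recording and a boolean channels x samples mask of
    samples whose filtered amplitude exceeds the artifact threshold.
    DC is retained (the passband starts at 0 Hz).
    """
    if raw.rate <= 2 * lowpass_hz:
        raise ValueError(
            f"rate {raw.rate} Hz too low for a {lowpass_hz} Hz passband")
    b, a = sps.butter(4, lowpass_hz / (raw.rate / 2.0), btype="low")
    x = sps.filtfilt(b, a, raw.samples, axis=-1)
    if 0 < line_freq < raw.rate / 2.0:
        bn, an = sps.iirnotch(line_freq, Q=30.0, fs=raw.rate)
        x = sps.filtfilt(bn, an, x, axis=-1)
    artifact_mask = np.abs(x) > artifact_threshold_uv
    return replace(raw, samples=x), artifact_mask


def epoch_eeg(raw: RawEEG,
              events: list[StimulusEvent],
              window: tuple[float, float] = EPOCH_WINDOW_S,
              artifact_mask: np.ndarray | None = None,
              channel_mask: ChannelMask | None = None) -> Epochs:
    """Cut one stimulus-locked epoch per event.

    Sample count per epoch is ``round((w1 - w0) * rate) + 1`` (inclusive
    endpoints). Epochs extending past the recording edges are dropped with
    a warning; epochs containing a marked artifact sample on any valid
    channel are rejected.
    """
    w0, w1 = window
    rate = raw.rate
    n_samp = int(round((w1 - w0) * rate)) + 1
    times = w0 + np.arange(n_samp) / rate
    ch_ok = (channel_mask.valid if channel_mask is not None
             else np.ones(raw.n_channels, bool))
    epochs, classes = [], []
    n_rej = n_edge = 0
    n_total = raw.samples.shape[1]
    for e in events:
        i0 = int(round((e.onset + w0) * rate))
        if i0 < 0 or i0 + n_samp > n_total:
            n_edge += 1
            continue
        if artifact_mask is not None and \
                artifact_mask[ch_ok, i0:i0 + n_samp].any():
            n_rej += 1
            continue
        epochs.append(raw.samples[:, i0:i0 + n_samp])
        classes.append(e.stimulus_class)
    if n_edge:
        logger.warning("%d events too close to recording edge, dropped",
                       n_edge)
    data = (np.stack(epochs) if epochs
            else np.empty((0, raw.n_channels, n_samp)))
    return Epochs(data=data, times=times, classes=classes,
                  labels=list(raw.labels), rate=rate, n_rejected=n_rej,
                  n_dropped_edge=n_edge)


def baseline_correct(epochs: Epochs) -> Epochs:
    """Subtract each trial/channel's prestimulus mean from the whole epoch."""
    pre = epochs.times < 0
    if not pre.any():
        raise ValueError("epoch window contains no prestimulus samples")
    base = epochs.data[:, :, pre].mean(axis=-1, keepdims=True)
    return replace(epochs, data=epochs.data - base,
                   baseline_corrected=True)


def average_erp(epochs: Epochs, stimulus_class: str) -> ERPResult:
    """Pointwise mean and SEM across trials of one class, per channel."""
    idx = [i for i, c in enumerate(epochs.classes)
           if c == stimulus_class]
    if not idx:
        raise ValueError(f"no epochs for class '{stimulus_class}'")
    sub = epochs.data[idx]
    k = len(idx)
    mean = sub.mean(axis=0)
    sem = (sub.std(axis=0, ddof=1) / np.sqrt(k) if k > 1
           else np.zeros_like(mean))
    return ERPResult(stimulus_class=stimulus_class, mean=mean, sem=sem,
                     times=epochs.times, labels=epochs.labels, n_trials=k)


def extract_p300(erp: ERPResult, channel: str,
                 window_ms: tuple[float, float] = P300_WINDOW_MS,
                 require_positive: bool = True) -> P300Peak:
    """Windowed maximum of the class-mean waveform at one channel.

    Latency is the time of the maximum (earliest sample on ties). When the
    windowed maximum is not strictly positive the peak is flagged
    (``positive=False``) rather than rejected.
    """
    if channel not in erp.labels:
        raise ValueError(f"unknown channel '{channel}'")
    ci = erp.labels.index(channel)
    t_ms = erp.times * 1000.0
    sel = (t_ms >= window_ms[0]) & (t_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("search window outside the epoch")
    wave = erp.mean[ci, sel]
    i = int(np.argmax(wave))          # argmax returns the earliest maximum
    amp = float(wave[i])
    lat = float(t_ms[sel][i])
    positive = amp > 0 or not require_positive
    return P300Peak(latency_ms=lat, amplitude_uv=amp, positive=positive)
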