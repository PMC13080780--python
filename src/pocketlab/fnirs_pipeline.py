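"""fNIRS processing: intensity → optical density → hemoglobin epochs.

Stages, in the order they run:

1. optical density ΔOD = −log10(I/I0), I0 per channel/wavelength
   (temporal mean of the recording, or of the first baseline only);
2. channel quality: scalp coupling index (SCI), the cardiac-band
   correlation of the two wavelength signals — channels with SCI < 0.4
   are pruned;
3. motion correction on OD: wavelet despiking (detail coefficients beyond
   k·IQR zeroed) followed by spline re-levelling of baseline-shift
   segments detected by a moving-SD criterion;
4. modified Beer-Lambert inversion to ΔHbO/ΔHbR (µM) per long channel;
5. zero-phase FIR low-pass at 0.08 Hz to suppress cardiac, respiratory
   and Mayer-wave oscillations;
6. short-channel regression: the nearest short channel (plus intercept)
   is fit to each long channel by ordinary least squares and the residual
   retained, removing scalp/skin hemodynamics;
7. event-locked epoching over −1 to +20 s with prestimulus baseline
   subtraction, class-wise mean/SEM and peak read-out.

With a 2 s ISI the 20 s epochs overlap by construction; the class means
are event-locked averages, not deconvolved responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import interpolate, signal as sps

from . import montage
from .eeg_pipeline import ChannelMask
from .synthetic_participant import (DEFAULT_DPF, EXTINCTION_COEFFS,
                                    RawFNIRS)
from .task_engine import TARGET, STANDARD, StimulusEvent

logger = logging.getLogger(__name__)

SCI_MIN = 0.4
SCI_CARDIAC_BAND_HZ = (0.5, 2.5)
FNIRS_LOWPASS_HZ = 0.08
FNIRS_STOP_HZ = 0.25
HBO_EPOCH_WINDOW_S = (-1.0, 20.0)


@dataclass
class OpticalDensity:
    data: np.ndarray              # channels x wavelengths(2) x samples
    rate: float
    channels: list[montage.FnirsChannel]
    wavelengths: tuple[float, float]


@dataclass
class HemoTimeSeries:
    hbo: np.ndarray               # µM, channels x samples
    hbr: np.ndarray               # µM, channels x samples
    rate: float
    channels: list[montage.FnirsChannel]
    short_regressed: bool = False
    regression_warning: str | None = None


@dataclass(frozen=True)
class MBLLParams:
    """Extinction coefficients (1/(mM·cm)) and pathlength factors."""

    extinction: dict[float, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in EXTINCTION_COEFFS.items()})
    dpf: dict[float, float] | float = DEFAULT_DPF

    def dpf_at(self, wavelength: float) -> float:
        if isinstance(self.dpf, dict):
            return self.dpf[wavelength]
        return float(self.dpf)

    def matrix(self, wavelengths: tuple[float, float]) -> np.ndarray:
        E = np.array([[self.extinction[w]["hbo"], self.extinction[w]["hbr"]]
                      for w in wavelengths])
        if np.linalg.cond(E) >= 100.0:
            raise ValueError("extinction matrix is ill-conditioned "
                             f"(cond {np.linalg.cond(E):.1f} >= 100)")
        return E


@dataclass
class ClassEpochStats:
    mean: np.ndarray              # channels x samples, µM
    sem: np.ndarray
    n_events: int
    peak_value: np.ndarray        # per channel
    peak_time: np.ndarray         # s post-stimulus, per channel


@dataclass
class HemoEpochResult:
    times: np.ndarray
    labels: list[str]
    per_class: dict[str, ClassEpochStats]
    n_dropped_edge: int = 0


def od_from_intensity(raw: RawFNIRS, i0_mode: str = "mean",
                      baseline_duration: float | None = None
                      ) -> OpticalDensity:
    """ΔOD = −log10(I/I0) per channel and wavelength.

    ``i0_mode='mean'`` uses the temporal mean of the whole recording;
    ``'first_baseline'`` uses the mean over the initial
    ``baseline_duration`` seconds only.
    """
    I = raw.intensities
    if np.any(I <= 0):
        raise ValueError("intensities must be strictly positive")
    if i0_mode == "mean":
        i0 = I.mean(axis=-1, keepdims=True)
    elif i0_mode == "first_baseline":
        if baseline_duration is None:
            raise ValueError("baseline_duration required for "
                             "i0_mode='first_baseline'")
        nb = max(1, int(round(baseline_duration * raw.rate)))
        i0 = I[:, :, :nb].mean(axis=-1, keepdims=True)
    else:
        raise ValueError(f"unknown i0_mode '{i0_mode}'")
    return OpticalDensity(data=-np.log10(I / i0), rate=raw.rate,
                          channels=list(raw.channels),
                          wavelengths=raw.wavelengths)


def scalp_coupling_index(raw: RawFNIRS,
                         cardiac_band: tuple[float, float]
                         = SCI_CARDIAC_BAND_HZ,
                         threshold: float = SCI_MIN
                         ) -> tuple[np.ndarray, ChannelMask]:
    """SCI per channel: cardiac-band correlation of the two wavelengths.

    Each wavelength's intensity is band-passed to the cardiac band and
    variance-normalized; the SCI is their zero-lag Pearson correlation.
    A channel is invalid iff SCI < ``threshold`` (strict). Zero-variance
    channels get an undefined SCI (NaN) and are invalid with a reason.
    """
    n = raw.intensities.shape[-1]
    if n < 10 * raw.rate:
        raise ValueError("recording shorter than 10 s: SCI unreliable")
    lo, hi = cardiac_band
    hi = min(hi, 0.99 * raw.rate / 2.0)
    b, a = sps.butter(3, [lo / (raw.rate / 2), hi / (raw.rate / 2)],
                      btype="band")
    sci = np.full(raw.n_channels, np.nan)
    valid = np.zeros(raw.n_channels, bool)
    reasons: list[str | None] = [None] * raw.n_channels
    for c in range(raw.n_channels):
        x = raw.intensities[c]
        if x[0].std() == 0 or x[1].std() == 0:
            reasons[c] = "zero-variance signal: SCI undefined"
            continue
        xf = sps.filtfilt(b, a, x, axis=-1)
        s0, s1 = xf[0].std(), xf[1].std()
        if s0 == 0 or s1 == 0:
            reasons[c] = "zero-variance cardiac band: SCI undefined"
            continue
        sci[c] = float(np.corrcoef(xf[0], xf[1])[0, 1])
        if sci[c] >= threshold:
            valid[c] = True
        else:
            reasons[c] = f"SCI {sci[c]:.2f} < {threshold:g}"
    return sci, ChannelMask(valid=valid, reasons=reasons)


def _wavelet_despike(x: np.ndarray, wavelet: str = "db4",
                     level: int | None = None, k: float = 1.5
                     ) -> np.ndarray:
    """Zero detail coefficients beyond k·IQR of their level; reconstruct."""
    max_level = pywt.dwt_max_level(len(x), pywt.Wavelet(wavelet).dec_len)
    level = min(level or 4, max_level)
    if level < 1:
        return x.copy()
    coeffs = pywt.wavedec(x, wavelet, level=level)
    out = [coeffs[0]]
    for c in coeffs[1:]:
        q1, q3 = np.percentile(c, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        c = c.copy()
        c[(c < lo) | (c > hi)] = 0.0
        out.append(c)
    rec = pywt.waverec(out, wavelet)
    return rec[:len(x)]


def _detect_shift_segments(x: np.ndarray, rate: float,
                           window_s: float = 1.0, k: float = 4.0
                           ) -> list[tuple[int, int]]:
    """Flag samples whose local SD of the derivative is anomalously high."""
    w = max(3, int(round(window_s * rate)))
    dx = np.abs(np.diff(x, prepend=x[0]))
    kern = np.ones(w) / w
    local = np.sqrt(np.convolve(dx ** 2, kern, mode="same"))
    ref = np.median(local)
    if ref == 0:
        return []
    flagged = local > k * ref
    segments = []
    i = 0
    n = len(x)
    while i < n:
        if flagged[i]:
            j = i
            while j < n and flagged[j]:
                j += 1
            a = max(0, i - w // 2)
            b = min(n, j + w // 2)
            if segments and a <= segments[-1][1]:
                segments[-1] = (segments[-1][0], b)
            else:
                segments.append((a, b))
            i = j
        else:
            i += 1
    return segments


def _spline_relevel(x: np.ndarray, segments: list[tuple[int, int]],
                    rate: float) -> np.ndarray:
    """Remove artifact-segment trends and re-anchor subsequent data.

    Within each flagged segment a smoothing spline captures the artifact
    shape (including any step); the residual is re-anchored to the level
    just before the segment, and all later samples are offset so the
    series stays continuous — a persistent baseline shift is thereby
    removed.
    """
    y = x.copy()
    offset = 0.0
    for a, b in segments:
        seg = x[a:b]
        t = np.arange(len(seg))
        if len(seg) >= 8:
            spl = interpolate.UnivariateSpline(
                t, seg, k=3, s=len(seg) * np.var(np.diff(seg)) * 0.5)
            trend = spl(t)
        else:
            trend = np.full(len(seg), seg.mean())
        resid = seg - trend
        level_before = y[a - 1] if a > 0 else x[0] - offset
        y[a:b] = resid - (resid[0] if len(resid) else 0.0) + level_before
        if b < len(x):
            # anchor everything after the segment to the corrected level
            offset = x[b] - (y[b - 1] + (x[b] - x[b - 1]))
            y[b:] = x[b:] - offset
    return y


def motion_correct(od: OpticalDensity, wavelet: str = "db4",
                   iqr_k: float = 1.5, shift_k: float = 4.0,
                   shift_window_s: float = 1.0) -> OpticalDensity:
    """Two-stage motion correction: wavelet despiking then spline
    re-levelling of detected baseline shifts. Shape-preserving."""
    out = np.empty_like(od.data)
    n_ch, n_wl, _ = od.data.shape
    for c in range(n_ch):
        for w in range(n_wl):
            x = _wavelet_despike(od.data[c, w], wavelet=wavelet, k=iqr_k)
            segs = _detect_shift_segments(x, od.rate, shift_window_s,
                                          shift_k)
            out[c, w] = _spline_relevel(x, segs, od.rate) if segs else x
    return replace(od, data=out)


def design_physiological_lowpass(rate: float,
                                 cutoff: float = FNIRS_LOWPASS_HZ,
                                 stop: float = FNIRS_STOP_HZ
                                 ) -> np.ndarray:
    """Linear-phase FIR taps: pass below ``cutoff``, ≥20 dB down at
    ``stop`` (per pass; zero-phase application doubles attenuation)."""
    if rate <= 2 * stop:
        raise ValueError(f"rate {rate} Hz too low for the filter band")
    width = (stop - cutoff) / (rate / 2.0)
    numtaps, beta = sps.kaiserord(40.0, width)
    numtaps |= 1  # odd length, symmetric
    return sps.firwin(numtaps, (cutoff + stop) / 2.0,
                      window=("kaiser", beta), fs=rate)


def lowpass_physiological(obj, rate: float | None = None,
                          cutoff: float = FNIRS_LOWPASS_HZ,
                          stop: float = FNIRS_STOP_HZ):
    """Zero-phase 0.08 Hz FIR low-pass; accepts OpticalDensity,
    HemoTimeSeries or a bare array (``rate`` required then)."""
    if isinstance(obj, OpticalDensity):
        taps = _checked_taps(obj.data.shape[-1], obj.rate, cutoff, stop)
        return replace(obj, data=sps.filtfilt(taps, [1.0], obj.data,
                                              axis=-1))
    if isinstance(obj, HemoTimeSeries):
        taps = _checked_taps(obj.hbo.shape[-1], obj.rate, cutoff, stop)
        return replace(obj,
                       hbo=sps.filtfilt(taps, [1.0], obj.hbo, axis=-1),
                       hbr=sps.filtfilt(taps, [1.0], obj.hbr, axis=-1))
    if rate is None:
        raise ValueError("rate required for array input")
    x = np.asarray(obj, dtype=float)
    taps = _checked_taps(x.shape[-1], rate, cutoff, stop)
    return sps.filtfilt(taps, [1.0], x, axis=-1)


def _checked_taps(n: int, rate: float, cutoff: float,
                  stop: float) -> np.ndarray:
    taps = design_physiological_lowpass(rate, cutoff, stop)
    if n < 3 * len(taps):
        raise ValueError(
            f"recording ({n} samples) shorter than 3 filter lengths "
            f"({3 * len(taps)})")
    return taps


def mbll(od: OpticalDensity, params: MBLLParams | None = None
         ) -> HemoTimeSeries:
    """Invert the modified Beer-Lambert law per channel and sample.

    Solves ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·L·DPF(λ) for the 2×2
    system at each sample; concentrations returned in µM.
    """
    params = params or MBLLParams()
    E = params.matrix(od.wavelengths)
    Einv = np.linalg.inv(E)
    n_ch, _, n = od.data.shape
    hbo = np.empty((n_ch, n))
    hbr = np.empty((n_ch, n))
    dpfs = np.array([params.dpf_at(w) for w in od.wavelengths])
    for c, ch in enumerate(od.channels):
        L = ch.separation_mm / 10.0   # cm
        scaled = od.data[c] / (L * dpfs[:, None])
        conc_mM = Einv @ scaled
        hbo[c] = conc_mM[0] * 1000.0
        hbr[c] = conc_mM[1] * 1000.0
    return HemoTimeSeries(hbo=hbo, hbr=hbr, rate=od.rate,
                          channels=list(od.channels))


def short_channel_regression(long: HemoTimeSeries,
                             short: HemoTimeSeries,
                             pairing: dict[str, str] | None = None,
                             short_mask: ChannelMask | None = None
                             ) -> HemoTimeSeries:
    """OLS residual of each long channel on its paired short channel.

    Pairing defaults to the nearest short channel by geometric midpoint.
    If every short channel is invalid the input is passed through with a
    prominent warning flag on the result.
    """
    short_names = [c.name for c in short.channels]
    ok = (short_mask.valid if short_mask is not None
          else np.ones(len(short_names), bool))
    if not ok.any():
        logger.warning("all short channels invalid: skin regression "
                       "SKIPPED, long channels returned uncorrected")
        return replace(long,
                       regression_warning="all short channels invalid: "
                                          "no skin correction applied")
    valid_short = [c for c, o in zip(short.channels, ok) if o]
    if pairing is None:
        pairing = montage.nearest_short_pairing(
            list(long.channels) + valid_short)

    def residual(y: np.ndarray, s: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.ones_like(s), s])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta

    hbo = np.empty_like(long.hbo)
    hbr = np.empty_like(long.hbr)
    valid_names = [c.name for c in valid_short]
    for i, ch in enumerate(long.channels):
        sname = pairing.get(ch.name)
        if sname not in valid_names:
            sname = valid_names[0]
        si = short_names.index(sname)
        hbo[i] = residual(long.hbo[i], short.hbo[si])
        hbr[i] = residual(long.hbr[i], short.hbr[si])
    return replace(long, hbo=hbo, hbr=hbr, short_regressed=True)


def split_long_short(hemo: HemoTimeSeries
                     ) -> tuple[HemoTimeSeries, HemoTimeSeries]:
    li = [i for i, c in enumerate(hemo.channels) if not c.is_short]
    si = [i for i, c in enumerate(hemo.channels) if c.is_short]
    mk = lambda idx: replace(hemo, hbo=hemo.hbo[idx], hbr=hemo.hbr[idx],
                             channels=[hemo.channels[i] for i in idx])
    return mk(li), mk(si)


def epoch_hbo(hemo: HemoTimeSeries,
              events: list[StimulusEvent],
              window: tuple[float, float] = HBO_EPOCH_WINDOW_S,
              classes: tuple[str, ...] = (TARGET, STANDARD)
              ) -> HemoEpochResult:
    """Event-locked HbO epochs: class-wise mean/SEM and peak read-out.

    Each epoch is baseline-corrected by its mean over [−1, 0) s. Events
    whose window extends past the recording are dropped with a warning.
    The peak value/time are taken from the class-mean waveform over the
    poststimulus part of the window.
    """
    w0, w1 = window
    rate = hemo.rate
    n_samp = int(round((w1 - w0) * rate)) + 1
    times = w0 + np.arange(n_samp) / rate
    pre = times < 0
    post = times >= 0
    n_total = hemo.hbo.shape[-1]
    by_class: dict[str, list[np.ndarray]] = {c: [] for c in classes}
    n_edge = 0
    for e in events:
        if e.stimulus_class not in by_class:
            continue
        i0 = int(round((e.onset + w0) * rate))
        if i0 < 0 or i0 + n_samp > n_total:
            n_edge += 1
            continue
        ep = hemo.hbo[:, i0:i0 + n_samp]
        ep = ep - ep[:, pre].mean(axis=-1, keepdims=True)
        by_class[e.stimulus_class].append(ep)
    if n_edge:
        logger.warning("%d events too close to recording end, dropped",
                       n_edge)
    per_class: dict[str, ClassEpochStats] = {}
    for klass, eps in by_class.items():
        if not eps:
            continue
        arr = np.stack(eps)
        k = arr.shape[0]
        mean = arr.mean(axis=0)
        sem = (arr.std(axis=0, ddof=1) / np.sqrt(k) if k > 1
               else np.zeros_like(mean))
        ipk = np.argmax(mean[:, post], axis=-1)
        per_class[klass] = ClassEpochStats(
            mean=mean, sem=sem, n_events=k,
            peak_value=mean[:, post][np.arange(mean.shape[0]), ipk],
            peak_time=times[post][ipk])
    return HemoEpochResult(times=times,
                           labels=[c.name for c in hemo.channels],
                           per_class=per_class, n_dropped_edge=n_edge)


def process_fnirs(raw: RawFNIRS,
                  events: list[StimulusEvent],
                  params: MBLLParams | None = None,
                  i0_mode: str = "mean",
                  baseline_duration: float | None = None,
                  window: tuple[float, float] = HBO_EPOCH_WINDOW_S,
                  sci_threshold: float = SCI_MIN
                  ) -> tuple[HemoEpochResult, HemoTimeSeries, ChannelMask]:
    """Full single-participant chain: OD → SCI mask → motion correction →
    MBLL → 0.08 Hz low-pass → short-channel regression → epoching.

    Returns the epochs (long channels), the corrected long-channel time
    series, and the all-channel SCI mask (ordered as ``raw.channels``).
    """
    od = od_from_intensity(raw, i0_mode=i0_mode,
                           baseline_duration=baseline_duration)
    _, mask = scalp_coupling_index(raw, threshold=sci_threshold)
    od = motion_correct(od)
    hemo = mbll(od, params)
    hemo = lowpass_physiological(hemo)
    long, short = split_long_short(hemo)
    short_idx = [i for i, c in enumerate(hemo.channels) if c.is_short]
    short_mask = ChannelMask(
        valid=mask.valid[short_idx],
        reasons=[mask.reasons[i] for i in short_idx])
    corrected = short_channel_regression(long, short,
                                         short_mask=short_mask)
    epochs = epoch_hbo(corrected, events, window=window)
    return epochs, corrected, mask
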