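"""Trial reconstruction, RT/accuracy summaries and the paired Wilcoxon test.

Responses are matched to stimuli by an attribution window: a button press
belongs to the latest stimulus that precedes it by more than the response
floor (anticipation cutoff, default 100 ms) and by no more than the ISI.
Accuracy counts omissions as errors (denominator = responded + omitted),
a documented convention since the source protocol leaves it open.

The group statistic is the Wilcoxon signed-rank test on per-participant
per-class mean RTs, in its normal-approximation form: zero differences
dropped, mid-ranks for tied magnitudes, tie-corrected variance, no
continuity correction by default, effect size r = Z/sqrt(n).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .task_engine import (TARGET, STANDARD, EventStreamSet,
                          StimulusEvent, stimulus_events_from_streams)

logger = logging.getLogger(__name__)

NONE = "none"


@dataclass(frozen=True)
class Trial:
    onset: float                # s
    stimulus_class: str         # TARGET or STANDARD
    response_button: str        # TARGET, STANDARD or NONE
    rt: float | None            # ms; present iff responded
    correct: bool | None        # present iff responded


@dataclass(frozen=True)
class ClassSummary:
    mean_rt: float
    sd_rt: float
    accuracy_pct: float
    n_trials: int
    n_omissions: int


@dataclass(frozen=True)
class BehaviorSummary:
    target: ClassSummary
    standard: ClassSummary

    def for_class(self, klass: str) -> ClassSummary:
        return self.target if klass == TARGET else self.standard


@dataclass(frozen=True)
class WilcoxonResult:
    n_pairs: int      # pairs used (zero differences dropped)
    w_plus: float     # positive-rank sum
    z: float
    p: float          # two-sided, standard normal
    r: float          # effect size z / sqrt(n)


def match_responses(stimulus_stream,
                    marker_stream,
                    isi: float = 2.0,
                    response_floor: float = 100.0) -> list[Trial]:
    """Attribute responses to stimuli and build the trial list.

    Parameters
    ----------
    stimulus_stream
        List of :class:`StimulusEvent`, or an :class:`EventStreamSet`
        (in which case both streams and the ISI are taken from it).
    marker_stream
        List of ``(timestamp, button)`` pairs / objects with ``timestamp``
        and ``button`` attributes; ignored when an ``EventStreamSet`` is
        passed as ``stimulus_stream``.
    response_floor
        Minimum credited RT in ms; earlier presses are anticipations and
        are left unattributed.

    A response is attributed to the latest stimulus whose onset precedes it
    by more than the floor and by at most the ISI; only the first response
    per stimulus is kept (duplicates resolved first-wins, with a warning).
    Stimuli without an attributed response become omissions.
    """
    if isinstance(stimulus_stream, EventStreamSet):
        streams = stimulus_stream
        from .task_engine import config_from_streams
        try:
            isi = config_from_streams(streams).isi
        except ValueError:
            pass
        events = stimulus_events_from_streams(streams)
        responses = []
        for r in streams.marker:
            f = r.fields()
            if "button" in f:
                responses.append((r.timestamp, f["button"]))
    else:
        events = sorted(stimulus_stream, key=lambda e: e.onset)
        responses = [(r.timestamp, r.button) if hasattr(r, "timestamp")
                     else (r[0], r[-1]) for r in marker_stream]
    responses = sorted(responses, key=lambda x: x[0])
    floor_s = response_floor / 1000.0

    attributed: dict[int, tuple[float, str]] = {}
    n_unattributed = 0
    n_duplicate = 0
    onsets = np.array([e.onset for e in events])
    for t_resp, button in responses:
        # latest stimulus with t_resp - onset in (floor, isi]
        i = int(np.searchsorted(onsets, t_resp - floor_s,
                                side="left")) - 1
        if i < 0 or t_resp - onsets[i] > isi:
            n_unattributed += 1
            continue
        if i in attributed:
            n_duplicate += 1
            continue
        attributed[i] = (t_resp, button)
    if n_unattributed:
        logger.warning("%d responses left unattributed", n_unattributed)
    if n_duplicate:
        logger.warning("%d duplicate responses dropped (first kept)",
                       n_duplicate)

    trials: list[Trial] = []
    for i, e in enumerate(events):
        if i in attributed:
            t_resp, button = attributed[i]
            rt = (t_resp - e.onset) * 1000.0
            trials.append(Trial(onset=e.onset,
                                stimulus_class=e.stimulus_class,
                                response_button=button, rt=rt,
                                correct=button == e.stimulus_class))
        else:
            trials.append(Trial(onset=e.onset,
                                stimulus_class=e.stimulus_class,
                                response_button=NONE, rt=None,
                                correct=None))
    return trials


def summarize_behavior(trials: list[Trial]) -> BehaviorSummary:
    """Per-class RT mean/SD (responded trials) and accuracy in percent.

    Accuracy = correct / (responded + omissions); omissions count as
    errors. Raises if either class has no trials.
    """
    out = {}
    for klass in (TARGET, STANDARD):
        sub = [t for t in trials if t.stimulus_class == klass]
        if not sub:
            raise ValueError(f"no trials for class '{klass}'")
        rts = np.array([t.rt for t in sub if t.rt is not None])
        n_omit = sum(1 for t in sub if t.response_button == NONE)
        n_correct = sum(1 for t in sub if t.correct)
        if rts.size == 0:
            raise ValueError(f"no responded trials for class '{klass}'")
        out[klass] = ClassSummary(
            mean_rt=float(rts.mean()),
            sd_rt=float(rts.std(ddof=1)) if rts.size > 1 else 0.0,
            accuracy_pct=100.0 * n_correct / len(sub),
            n_trials=len(sub),
            n_omissions=n_omit)
    return BehaviorSummary(target=out[TARGET], standard=out[STANDARD])


def wilcoxon_signed_rank(x, y, continuity: bool = False) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test, normal approximation.

    Differences of zero are dropped; tied magnitudes receive mid-ranks and
    the tie correction sum(t^3 - t)/48 is subtracted from the variance.
    Z = (W+ − n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 − tie term); the two-sided
    p comes from the standard normal and r = Z/sqrt(n). The continuity
    correction (±0.5 toward the mean) is off by default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: test degenerate")
    if n < 5:
        logger.warning("only %d nonzero pairs: normal approximation is "
                       "unreliable below n=5", n)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / 48.0)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise ValueError("zero variance: all magnitudes tied at one value")
    num = w_plus - mu
    if continuity:
        num -= 0.5 * np.sign(num)
    z = num / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return WilcoxonResult(n_pairs=n, w_plus=w_plus, z=float(z),
                          p=float(p), r=float(z / math.sqrt(n)))
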