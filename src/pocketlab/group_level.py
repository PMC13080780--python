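"""Cohort aggregation: ROI averaging, grand averages and the study report.

Per-participant channel results are first averaged within named regions of
interest (valid channels only), then averaged across participants
(pointwise mean with SEM = across-participant SD / sqrt(n)). A participant
is dropped from a modality when more than half of that modality's channels
are invalid. The cohort report collects the behavioral table, the Wilcoxon
test on per-participant mean RTs, the P300 peak table at Cz/Pz, the
right-frontal HbO class means and the exclusion log, as CSV/JSON plus
waveform figures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import montage
from .behavioral_analysis import BehaviorSummary, wilcoxon_signed_rank
from .eeg_pipeline import ChannelMask, P300Peak
from .task_engine import TARGET, STANDARD

logger = logging.getLogger(__name__)

PARTICIPANT_EXCLUSION_FRACTION = 0.5


@dataclass(frozen=True)
class ROIMap:
    """Named channel groups per modality, with label aliases resolved."""

    eeg: dict[str, list[str]]
    fnirs: dict[str, list[str]]

    @classmethod
    def default(cls) -> "ROIMap":
        return cls(eeg={k: list(v) for k, v in montage.EEG_ROI_MAP.items()},
                   fnirs={k: list(v)
                          for k, v in montage.FNIRS_ROI_MAP.items()})

    def eeg_roi(self, label: str) -> list[str]:
        return self.eeg[montage.resolve_roi(label)]

    def fnirs_roi(self, label: str) -> list[str]:
        return self.fnirs[montage.resolve_roi(label)]


@dataclass
class GrandAverage:
    """Across-participant mean waveform per class/ROI with SEM."""

    times: np.ndarray
    per_class: dict[str, dict[str, np.ndarray]]      # class -> roi -> mean
    per_class_sem: dict[str, dict[str, np.ndarray]]  # class -> roi -> sem
    n_participants: dict[str, dict[str, int]]
    sem_defined: bool = True


def roi_average(waveforms: np.ndarray,
                labels: list[str],
                mask: ChannelMask | None,
                roi_map: dict[str, list[str]]
                ) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Average channel waveforms within each ROI over valid members.

    ``waveforms`` is channels x samples, indexed by ``labels``. Returns the
    per-ROI waveforms and a reason dict for ROIs absent because no member
    channel is valid. Unknown channel labels in the map raise.
    """
    index = {lab: i for i, lab in enumerate(labels)}
    valid = (mask.valid if mask is not None
             else np.ones(len(labels), bool))
    out: dict[str, np.ndarray] = {}
    missing: dict[str, str] = {}
    for roi, chans in roi_map.items():
        idx = []
        for ch in chans:
            if ch not in index:
                raise ValueError(f"ROI '{roi}' references unknown channel "
                                 f"'{ch}'")
            if valid[index[ch]]:
                idx.append(index[ch])
        if not idx:
            missing[roi] = "no valid member channels"
            continue
        out[roi] = waveforms[idx].mean(axis=0)
    return out, missing


def grand_average(per_participant: list[dict[str, dict[str, np.ndarray]]],
                  times: np.ndarray) -> GrandAverage:
    """Pointwise across-participant mean and SEM of per-ROI waveforms.

    ``per_participant`` holds one ``{class: {roi: waveform}}`` dict per
    participant; an ROI absent for a participant simply does not
    contribute. With a single contributing participant the mean is
    returned and the SEM flagged undefined.
    """
    if not per_participant:
        raise ValueError("no participants")
    classes = sorted({c for p in per_participant for c in p})
    means: dict[str, dict[str, np.ndarray]] = {}
    sems: dict[str, dict[str, np.ndarray]] = {}
    ns: dict[str, dict[str, int]] = {}
    sem_defined = True
    for klass in classes:
        rois = sorted({r for p in per_participant
                       for r in p.get(klass, {})})
        means[klass], sems[klass], ns[klass] = {}, {}, {}
        for roi in rois:
            stack = np.stack([p[klass][roi] for p in per_participant
                              if roi in p.get(klass, {})])
            n = stack.shape[0]
            means[klass][roi] = stack.mean(axis=0)
            ns[klass][roi] = n
            if n > 1:
                sems[klass][roi] = stack.std(axis=0, ddof=1) / np.sqrt(n)
            else:
                sems[klass][roi] = np.zeros_like(means[klass][roi])
                sem_defined = False
    return GrandAverage(times=times, per_class=means, per_class_sem=sems,
                        n_participants=ns, sem_defined=sem_defined)


def participant_excluded(mask: ChannelMask,
                         fraction: float = PARTICIPANT_EXCLUSION_FRACTION
                         ) -> bool:
    """True when more than ``fraction`` of the channels are invalid."""
    return mask.n_invalid > fraction * len(mask)


@dataclass
class CohortResults:
    """Everything the report consumes. Any modality may be None."""

    behavior: list[BehaviorSummary] | None = None
    eeg_grand: GrandAverage | None = None            # ERP, channel-level Cz/Pz
    eeg_peaks: dict[str, dict[str, P300Peak]] | None = None
    hbo_grand: GrandAverage | None = None
    exclusions: list[dict] | None = None


def cohort_report(results: CohortResults, out_dir: str | Path,
                  make_figures: bool = True,
                  continuity: bool = False) -> dict:
    """Write the cohort report (CSV/JSON + figures); return its summary.

    Sections: (1) per-class RT/accuracy table, (2) Wilcoxon signed-rank on
    per-participant mean RTs, (3) P300 peak table at Cz and Pz, (4)
    right-frontal HbO class means with peak time, (5) exclusion log.
    Missing modalities yield explicit gaps, not errors.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"sections_missing": []}

    if results.behavior:
        rows = []
        for i, b in enumerate(results.behavior):
            for klass in (TARGET, STANDARD):
                s = b.for_class(klass)
                rows.append({"participant": i + 1, "class": klass,
                             "mean_rt_ms": s.mean_rt, "sd_rt_ms": s.sd_rt,
                             "accuracy_pct": s.accuracy_pct,
                             "n_trials": s.n_trials,
                             "n_omissions": s.n_omissions})
        df = pd.DataFrame(rows)
        df.to_csv(out_dir / "behavior_per_participant.csv", index=False)
        tgt = df[df["class"] == TARGET]
        std = df[df["class"] == STANDARD]
        rt_table = {
            "target": {"mean_rt_ms": float(tgt["mean_rt_ms"].mean()),
                       "sd_rt_ms": float(tgt["mean_rt_ms"].std(ddof=1)),
                       "accuracy_pct": float(tgt["accuracy_pct"].mean()),
                       "accuracy_sd": float(tgt["accuracy_pct"].std(ddof=1))},
            "standard": {"mean_rt_ms": float(std["mean_rt_ms"].mean()),
                         "sd_rt_ms": float(std["mean_rt_ms"].std(ddof=1)),
                         "accuracy_pct": float(std["accuracy_pct"].mean()),
                         "accuracy_sd": float(std["accuracy_pct"].std(ddof=1))},
        }
        wres = wilcoxon_signed_rank(tgt["mean_rt_ms"].to_numpy(),
                                    std["mean_rt_ms"].to_numpy(),
                                    continuity=continuity)
        summary["behavior"] = rt_table
        summary["wilcoxon"] = asdict(wres)
        summary["n_behavior_participants"] = len(results.behavior)
    else:
        summary["sections_missing"].append("behavior")

    if results.eeg_peaks is not None:
        summary["p300"] = {
            ch: {klass: asdict(pk) for klass, pk in d.items()}
            for ch, d in results.eeg_peaks.items()}
    else:
        summary["sections_missing"].append("eeg")

    if results.hbo_grand is not None:
        ga = results.hbo_grand
        roi = "frontal_right"
        hbo = {}
        for klass in ga.per_class:
            if roi not in ga.per_class[klass]:
                continue
            wave = ga.per_class[klass][roi]
            post = ga.times >= 0
            i = int(np.argmax(wave[post]))
            hbo[klass] = {"peak_um": float(wave[post][i]),
                          "peak_time_s": float(ga.times[post][i]),
                          "n_participants": ga.n_participants[klass][roi]}
        summary["hbo_frontal_right"] = hbo
        _dump_grand_csv(ga, out_dir / "hbo_roi_grand_average.csv")
    else:
        summary["sections_missing"].append("fnirs")

    if results.eeg_grand is not None:
        _dump_grand_csv(results.eeg_grand,
                        out_dir / "erp_grand_average.csv")

    summary["exclusions"] = results.exclusions or []
    (out_dir / "report.json").write_text(
        json.dumps(summary, indent=1, default=_jsonable))

    if make_figures:
        _figures(results, out_dir)
    return summary


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, np.bool_):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def _dump_grand_csv(ga: GrandAverage, path: Path) -> None:
    cols = {"time_s": ga.times}
    for klass, rois in ga.per_class.items():
        for roi, wave in rois.items():
            cols[f"{klass}:{roi}"] = wave
            cols[f"{klass}:{roi}:sem"] = ga.per_class_sem[klass][roi]
    pd.DataFrame(cols).to_csv(path, index=False)


def _figures(results: CohortResults, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {TARGET: "tab:red", STANDARD: "tab:blue"}
    if results.eeg_grand is not None:
        ga = results.eeg_grand
        rois = sorted({r for d in ga.per_class.values() for r in d})
        for roi in rois:
            fig, ax = plt.subplots(figsize=(6, 4))
            for klass, d in ga.per_class.items():
                if roi not in d:
                    continue
                m, s = d[roi], ga.per_class_sem[klass][roi]
                ax.plot(ga.times * 1000, m, color=colors.get(klass),
                        label=klass)
                ax.fill_between(ga.times * 1000, m - s, m + s,
                                color=colors.get(klass), alpha=0.25)
            ax.set_xlabel("time (ms)")
            ax.set_ylabel("amplitude (µV)")
            ax.set_title(f"grand-average ERP, {roi}")
            ax.legend()
            fig.tight_layout()
            fig.savefig(out_dir / f"erp_{roi}.png", dpi=100)
            plt.close(fig)
    if results.hbo_grand is not None:
        ga = results.hbo_grand
        rois = sorted({r for d in ga.per_class.values() for r in d})
        for roi in rois:
            fig, ax = plt.subplots(figsize=(6, 4))
            for klass, d in ga.per_class.items():
                if roi not in d:
                    continue
                m, s = d[roi], ga.per_class_sem[klass][roi]
                ax.plot(ga.times, m, color=colors.get(klass), label=klass)
                ax.fill_between(ga.times, m - s, m + s,
                                color=colors.get(klass), alpha=0.25)
            ax.set_xlabel("time (s)")
            ax.set_ylabel("ΔHbO (µM)")
            ax.set_title(f"grand-average HbO, {roi}")
            ax.legend()
            fig.tight_layout()
            fig.savefig(out_dir / f"hbo_{roi}.png", dpi=100)
            plt.close(fig)
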