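"""End-to-end replication run: cohort simulation through cohort report.

``run_replication`` simulates a cohort for the default oddball protocol,
pushes every participant through the behavioral, ERP and hemoglobin
pipelines, applies the channel- and participant-level validity rules,
aggregates ROI grand averages and writes the report. Fully deterministic
given the master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import group_level as gl
from .behavioral_analysis import (BehaviorSummary, match_responses,
                                  summarize_behavior)
from .config import RunConfig
from .eeg_pipeline import (ChannelMask, ERPResult, average_erp,
                           baseline_correct, epoch_eeg, extract_p300,
                           preprocess_eeg, validate_channels_eeg)
from .fnirs_pipeline import process_fnirs
from .synthetic_participant import ParticipantData, simulate_cohort
from .task_engine import TARGET, STANDARD

logger = logging.getLogger(__name__)

MIDLINE_CHANNELS = ("Cz", "Pz")


@dataclass
class ParticipantAnalysis:
    participant_id: str
    behavior: BehaviorSummary | None
    erp_rois: dict[str, dict[str, np.ndarray]] | None  # class -> roi -> wave
    erp_times: np.ndarray | None
    eeg_mask: ChannelMask | None
    eeg_excluded: bool
    hbo_rois: dict[str, dict[str, np.ndarray]] | None
    hbo_times: np.ndarray | None
    fnirs_excluded: bool


def analyze_participant(data: ParticipantData, config: RunConfig
                        ) -> ParticipantAnalysis:
    pipe = config.pipeline
    roi_map = gl.ROIMap.default()
    events = list(data.schedule.events)

    trials = match_responses(data.streams,
                             None,
                             response_floor=pipe.response_floor_ms)
    behavior = summarize_behavior(trials)

    erp_rois = erp_times = eeg_mask = None
    eeg_excluded = False
    if data.eeg is not None:
        eeg_mask = validate_channels_eeg(data.eeg.impedances,
                                         pipe.impedance_max_kohm)
        eeg_excluded = gl.participant_excluded(
            eeg_mask, pipe.participant_exclusion_fraction)
        if not eeg_excluded:
            filt, artifacts = preprocess_eeg(
                data.eeg, lowpass_hz=pipe.eeg_lowpass_hz,
                line_freq=pipe.eeg_line_freq_hz,
                artifact_threshold_uv=pipe.eeg_artifact_uv)
            epochs = epoch_eeg(filt, events,
                               window=pipe.eeg_epoch_window_s,
                               artifact_mask=artifacts,
                               channel_mask=eeg_mask)
            epochs = baseline_correct(epochs)
            erp_rois = {}
            for klass in (TARGET, STANDARD):
                erp = average_erp(epochs, klass)
                rois, _ = gl.roi_average(erp.mean, erp.labels, eeg_mask,
                                         roi_map.eeg)
                erp_rois[klass] = rois
                erp_times = erp.times

    hbo_rois = hbo_times = None
    fnirs_excluded = False
    fnirs_mask = None
    if data.fnirs is not None:
        hbo_epochs, _, fnirs_mask = process_fnirs(
            data.fnirs, events,
            i0_mode=pipe.i0_mode,
            baseline_duration=data.schedule.config.baseline_duration,
            window=pipe.hbo_epoch_window_s,
            sci_threshold=pipe.sci_min)
        fnirs_excluded = gl.participant_excluded(
            fnirs_mask, pipe.participant_exclusion_fraction)
        if not fnirs_excluded:
            long_names = set(hbo_epochs.labels)
            all_names = [c.name for c in data.fnirs.channels]
            long_idx = [i for i, nm in enumerate(all_names)
                        if nm in long_names]
            long_mask = ChannelMask(
                valid=fnirs_mask.valid[long_idx],
                reasons=[fnirs_mask.reasons[i] for i in long_idx])
            hbo_rois = {}
            for klass, stats in hbo_epochs.per_class.items():
                rois, _ = gl.roi_average(stats.mean, hbo_epochs.labels,
                                         long_mask, roi_map.fnirs)
                hbo_rois[klass] = rois
                hbo_times = hbo_epochs.times

    return ParticipantAnalysis(
        participant_id=data.participant_id, behavior=behavior,
        erp_rois=erp_rois, erp_times=erp_times, eeg_mask=eeg_mask,
        eeg_excluded=eeg_excluded, hbo_rois=hbo_rois, hbo_times=hbo_times,
        fnirs_excluded=fnirs_excluded)


def _midline_erp_grand(analyses: list[ParticipantAnalysis]
                       ) -> tuple[gl.GrandAverage | None,
                                  dict[str, dict] | None]:
    contributing = [a for a in analyses
                    if a.erp_rois is not None]
    if not contributing:
        return None, None
    ga = gl.grand_average([a.erp_rois for a in contributing],
                          contributing[0].erp_times)
    # peak read-out at the midline single-electrode ROIs
    label_for = {"Cz": "temporal_midline", "Pz": "parietal_midline"}
    peaks: dict[str, dict] = {}
    for ch, roi in label_for.items():
        peaks[ch] = {}
        for klass in ga.per_class:
            if roi not in ga.per_class[klass]:
                continue
            erp = ERPResult(stimulus_class=klass,
                            mean=ga.per_class[klass][roi][None, :],
                            sem=ga.per_class_sem[klass][roi][None, :],
                            times=ga.times, labels=[ch],
                            n_trials=ga.n_participants[klass][roi])
            peaks[ch][klass] = extract_p300(erp, ch)
    return ga, peaks


def run_replication(config: RunConfig, out_dir: str | Path | None = None,
                    make_figures: bool = True,
                    with_eeg: bool = True, with_fnirs: bool = True
                    ) -> dict:
    """Simulate, analyze and report one full validation experiment.

    Returns the report summary dict (also written to ``out_dir`` as
    ``report.json`` with its CSV tables and figures).
    """
    config.validate()
    out_dir = Path(out_dir if out_dir is not None else config.output)
    logger.info("simulating cohort: n=%d seed=%d",
                config.cohort.n_participants, config.seed)
    cohort = simulate_cohort(
        config.cohort.n_participants, task_config=config.task,
        base_profile=config.profile,
        distribution=config.cohort.distribution, noise=config.noise,
        seed=config.seed, eeg_rate=config.cohort.eeg_rate,
        fnirs_rate=config.cohort.fnirs_rate,
        with_eeg=with_eeg, with_fnirs=with_fnirs)
    analyses = [analyze_participant(d, config) for d in cohort]

    exclusions = []
    for a in analyses:
        if a.eeg_excluded:
            exclusions.append({"participant": a.participant_id,
                               "modality": "eeg",
                               "reason": ">50% channels invalid"})
        if a.fnirs_excluded:
            exclusions.append({"participant": a.participant_id,
                               "modality": "fnirs",
                               "reason": ">50% channels invalid"})
        if a.eeg_mask is not None and a.eeg_mask.n_invalid:
            exclusions.append({"participant": a.participant_id,
                               "modality": "eeg",
                               "reason": "channels pruned",
                               "n_channels": a.eeg_mask.n_invalid})
    eeg_grand, eeg_peaks = _midline_erp_grand(analyses)

    hbo_contrib = [a for a in analyses if a.hbo_rois is not None]
    hbo_grand = None
    if hbo_contrib:
        hbo_grand = gl.grand_average([a.hbo_rois for a in hbo_contrib],
                                     hbo_contrib[0].hbo_times)

    results = gl.CohortResults(
        behavior=[a.behavior for a in analyses if a.behavior],
        eeg_grand=eeg_grand, eeg_peaks=eeg_peaks, hbo_grand=hbo_grand,
        exclusions=exclusions)
    summary = gl.cohort_report(results, out_dir,
                               make_figures=make_figures,
                               continuity=config.pipeline
                               .wilcoxon_continuity)
    return summary
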