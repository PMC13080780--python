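"""Forward-model properties: behavior, EEG and fNIRS generators."""

import dataclasses

import numpy as np
import pytest

from pocketlab import montage
from pocketlab.behavioral_analysis import wilcoxon_signed_rank
from pocketlab.fnirs_pipeline import mbll, od_from_intensity
from pocketlab.synthetic_participant import (
    CohortDistribution, NoiseModel, ParticipantProfile, double_gamma_hrf,
    lognormal_params, simulate_cohort, simulate_eeg, simulate_fnirs,
    simulate_responses)
from pocketlab.task_engine import (STANDARD, TARGET, TaskConfig,
                                   generate_oddball_schedule)


class TestProfiles:
    @pytest.mark.parametrize("kwargs", [
        {"rt_sd_target": 0.0}, {"acc_target": 1.2},
        {"p300_amp_target": float("nan")},
    ])
    def test_invalid_profile_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ParticipantProfile(**kwargs)

    def test_noise_frequencies_validated_against_nyquist(self):
        NoiseModel().check_rates(250.0, 10.0)
        with pytest.raises(ValueError):
            NoiseModel(cardiac_freq=6.0).check_rates(250.0, 10.0)


class TestResponses:
    def test_perfect_accuracy_matches_every_class(self, default_schedule,
                                                  rng):
        prof = ParticipantProfile(acc_target=1.0, acc_standard=1.0)
        resp = simulate_responses(default_schedule, prof, rng)
        by_onset = {e.onset: e.stimulus_class
                    for e in default_schedule.events}
        for r in resp:
            onset = max(o for o in by_onset if o < r.timestamp)
            assert r.button == by_onset[onset]

    def test_target_rt_mean_matches_lognormal_oracle(self):
        # ~10,000 target trials against the moment-matched lognormal
        prof = ParticipantProfile()
        mu, sigma = lognormal_params(prof.rt_mean_target,
                                     prof.rt_sd_target)
        oracle = np.exp(mu + sigma ** 2 / 2)
        assert oracle == pytest.approx(718.0, rel=1e-12)
        cfg = TaskConfig(gap_min=1, gap_max=1, task_duration=240.0)
        rng = np.random.default_rng(99)
        rts = []
        for seed in range(170):
            sched = generate_oddball_schedule(
                dataclasses.replace(cfg, seed=seed))
            classes = {e.onset: e.stimulus_class for e in sched.events}
            for r in simulate_responses(sched, prof, rng):
                onset = max(o for o in classes if o < r.timestamp)
                if classes[onset] == TARGET:
                    rts.append((r.timestamp - onset) * 1000.0)
        assert len(rts) > 9000
        se = prof.rt_sd_target / np.sqrt(len(rts))
        assert abs(np.mean(rts) - 718.0) < 3 * se

    def test_cohort_target_slower_than_standard(self, default_schedule,
                                                rng):
        prof = ParticipantProfile()
        resp = simulate_responses(default_schedule, prof, rng)
        classes = {e.onset: e.stimulus_class
                   for e in default_schedule.events}
        rt = {TARGET: [], STANDARD: []}
        for r in resp:
            onset = max(o for o in classes if o < r.timestamp)
            rt[classes[onset]].append((r.timestamp - onset) * 1000.0)
        assert np.mean(rt[TARGET]) > np.mean(rt[STANDARD])


class TestEEG:
    def test_zero_noise_zero_amplitude_gives_silence(
            self, default_schedule, quiet_noise, rng):
        prof = ParticipantProfile(p300_amp_target=0.0,
                                  p300_amp_standard=0.0)
        raw = simulate_eeg(default_schedule, prof, quiet_noise, rng)
        assert np.all(raw.samples == 0.0)

    def test_sample_count_covers_baselines_and_task(
            self, default_schedule, quiet_noise, rng):
        raw = simulate_eeg(default_schedule, ParticipantProfile(),
                           quiet_noise, rng)
        assert raw.samples.shape == (32, 250 * (10 + 240 + 10))
        assert set(raw.labels) == set(montage.EEG_CHANNELS)

    def test_noise_free_cz_peak_equals_configured_amplitude(
            self, default_schedule, quiet_noise, rng):
        # forward construction equals the extraction oracle
        amp, lat = 4.2, 356.0
        prof = ParticipantProfile(p300_amp_target=amp,
                                  p300_amp_standard=0.0,
                                  p300_latency=lat)
        raw = simulate_eeg(default_schedule, prof, quiet_noise, rng)
        cz = raw.labels.index("Cz")
        e = next(ev for ev in default_schedule.events
                 if ev.stimulus_class == TARGET)
        i = int(round((e.onset + lat / 1000.0) * raw.rate))
        assert raw.samples[cz, i] == pytest.approx(amp, rel=1e-6)
        assert raw.samples[cz, i] == pytest.approx(
            raw.samples[cz].max(), rel=1e-9)

    def test_signal_superposition_is_linear(self, default_schedule,
                                            quiet_noise):
        def run(amp):
            prof = ParticipantProfile(p300_amp_target=amp,
                                      p300_amp_standard=0.0)
            return simulate_eeg(default_schedule, prof, quiet_noise,
                                np.random.default_rng(3)).samples
        np.testing.assert_allclose(run(1.0) + run(2.0), run(3.0),
                                   atol=1e-10)


class TestFNIRS:
    def test_forward_inverse_round_trip_is_exact(self, default_schedule,
                                                 quiet_noise, rng):
        raw = simulate_fnirs(default_schedule, ParticipantProfile(),
                             quiet_noise, rng)
        od = od_from_intensity(raw, i0_mode="first_baseline",
                               baseline_duration=10.0)
        hemo = mbll(od)
        rf = montage.FNIRS_ROI_MAP["frontal_right"]
        idx = [i for i, c in enumerate(raw.channels) if c.name in rf]
        hrf = double_gamma_hrf(raw.rate, 9.0)
        train = np.zeros(raw.intensities.shape[2])
        for e in default_schedule.events:
            if e.stimulus_class == TARGET:
                train[int(round(e.onset * raw.rate))] = 0.2
        from scipy.signal import fftconvolve
        truth = fftconvolve(train, hrf)[:len(train)]
        scale = np.abs(truth).max()
        for i in idx:
            assert np.abs(hemo.hbo[i] - truth).max() / scale < 1e-9
            assert np.abs(hemo.hbr[i] + truth / 3.0).max() / scale < 1e-9

    def test_channel_inventory_43_long_8_short(self, default_schedule,
                                               quiet_noise, rng):
        raw = simulate_fnirs(default_schedule, ParticipantProfile(),
                             quiet_noise, rng)
        assert len(raw.long_idx) == 43
        assert len(raw.short_idx) == 8
        assert np.all(raw.intensities > 0)

    def test_short_channels_carry_no_event_locked_response(
            self, default_schedule, quiet_noise, rng):
        raw = simulate_fnirs(default_schedule, ParticipantProfile(),
                             quiet_noise, rng)
        flat = raw.intensities[raw.short_idx]
        assert np.all(np.ptp(flat, axis=-1) == 0.0)

    def test_hrf_peaks_at_configured_time(self):
        h = double_gamma_hrf(10.0, peak_time=9.0)
        assert np.argmax(h) / 10.0 == pytest.approx(9.0, abs=0.1)
        assert h.max() == pytest.approx(1.0)
        assert h.min() < 0.0  # undershoot


class TestCohort:
    def test_single_participant_directory_layout(self, tmp_path):
        simulate_cohort(1, seed=5, out_dir=tmp_path,
                        task_config=TaskConfig(task_duration=60.0))
        pdir = tmp_path / "sub-001"
        assert (pdir / "events.jsonl").exists()
        assert (pdir / "eeg.dat").exists() and (pdir / "eeg.json").exists()
        assert (pdir / "fnirs.dat").exists() \
            and (pdir / "fnirs.json").exists()

    def test_same_master_seed_reproduces_cohort(self):
        cfg = TaskConfig(task_duration=60.0)
        a = simulate_cohort(2, task_config=cfg, seed=11,
                            with_fnirs=False)
        b = simulate_cohort(2, task_config=cfg, seed=11,
                            with_fnirs=False)
        for pa, pb in zip(a, b):
            assert pa.schedule == pb.schedule
            assert pa.profile == pb.profile
            np.testing.assert_array_equal(pa.eeg.samples, pb.eeg.samples)

    def test_53_participant_rt_differences_all_positive(self):
        # profile-level effect (176 ms, SD 25) dwarfs its spread: with no
        # trial noise, all 53 target-standard differences come out positive
        # and the signed-rank Z hits the all-positive closed form
        cohort = simulate_cohort(53, seed=123, with_eeg=False,
                                 with_fnirs=False)
        t = np.array([p.profile.rt_mean_target for p in cohort])
        s = np.array([p.profile.rt_mean_standard for p in cohort])
        assert np.all(t - s > 0)
        res = wilcoxon_signed_rank(t, s)
        n = 53
        closed_form = (n * (n + 1) / 4) / np.sqrt(
            n * (n + 1) * (2 * n + 1) / 24)
        assert res.z == pytest.approx(closed_form)
        assert round(res.z, 2) == 6.33

    def test_monotonic_p300_amplitude_recovery(self, default_schedule,
                                               quiet_noise):
        # stronger configured ERP -> strictly larger extracted amplitude
        from pocketlab.eeg_pipeline import (average_erp, baseline_correct,
                                            epoch_eeg, extract_p300)
        amps = []
        for amp in (1.0, 2.5, 5.0):
            prof = ParticipantProfile(p300_amp_target=amp)
            raw = simulate_eeg(default_schedule, prof, quiet_noise,
                               np.random.default_rng(0))
            epochs = baseline_correct(
                epoch_eeg(raw, list(default_schedule.events)))
            erp = average_erp(epochs, TARGET)
            amps.append(extract_p300(erp, "Cz").amplitude_uv)
        assert amps[0] < amps[1] < amps[2]
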