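"""fNIRS quality pruning, motion correction, filtering, MBLL and epochs."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import fftconvolve

from pocketlab import montage
from pocketlab.fnirs_pipeline import (
    HemoTimeSeries, MBLLParams, OpticalDensity, epoch_hbo,
    lowpass_physiological, mbll, motion_correct, od_from_intensity,
    scalp_coupling_index, short_channel_regression, split_long_short)
from pocketlab.synthetic_participant import (RawFNIRS, double_gamma_hrf)
from pocketlab.task_engine import STANDARD, TARGET, StimulusEvent


def _channels(n_long=2, n_short=1):
    base = montage.fnirs_channels()
    longs = [c for c in base if not c.is_short][:n_long]
    shorts = [c for c in base if c.is_short][:n_short]
    return longs + shorts


def _raw(intens, rate=10.0, channels=None):
    intens = np.asarray(intens, float)
    if channels is None:
        channels = _channels(intens.shape[0] - 1, 1)
    return RawFNIRS(intensities=intens, rate=rate, channels=channels)


def _od(data, rate=10.0, channels=None):
    data = np.asarray(data, float)
    if channels is None:
        channels = _channels(data.shape[0], 0)
    return OpticalDensity(data=data, rate=rate, channels=channels,
                          wavelengths=(760.0, 850.0))


class TestSCI:
    def test_identical_cardiac_signal_gives_unit_sci(self):
        t = np.arange(600) / 10.0
        s = 100.0 + np.sin(2 * np.pi * 1.2 * t)
        intens = np.stack([np.stack([s, s])] * 3)
        sci, mask = scalp_coupling_index(_raw(intens))
        np.testing.assert_allclose(sci, 1.0, atol=1e-12)
        assert mask.valid.all()

    def test_independent_noise_fails_threshold(self):
        rng = np.random.default_rng(42)
        intens = 100.0 + rng.standard_normal((3, 2, 600))
        sci, mask = scalp_coupling_index(_raw(intens))
        assert np.all(np.abs(sci) < 0.4)
        assert not mask.valid.any()
        assert all("SCI" in r for r in mask.reasons)

    def test_sci_equal_to_threshold_is_valid(self):
        # strict < rule: a channel sitting exactly on the threshold passes
        t = np.arange(600) / 10.0
        s = 100.0 + np.sin(2 * np.pi * 1.2 * t)
        intens = np.stack([np.stack([s, s])])
        sci, mask = scalp_coupling_index(_raw(intens, channels=_channels(0, 1)),
                                         threshold=1.0)
        assert sci[0] == 1.0
        assert mask.valid[0]

    def test_zero_variance_channel_invalid_with_reason(self):
        intens = np.full((1, 2, 600), 100.0)
        sci, mask = scalp_coupling_index(
            _raw(intens, channels=_channels(0, 1)))
        assert np.isnan(sci[0])
        assert not mask.valid[0]
        assert "undefined" in mask.reasons[0]

    def test_sci_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(1)
        t = np.arange(600) / 10.0
        card = np.sin(2 * np.pi * 1.1 * t)
        w0 = 100.0 + card + 0.3 * rng.standard_normal(600)
        w1 = 100.0 + card + 0.3 * rng.standard_normal(600)
        a = np.stack([np.stack([w0, w1])])
        b = np.stack([np.stack([5.0 * w0 + 30.0, 0.25 * w1 + 2.0])])
        chans = _channels(1, 0)
        sci_a, _ = scalp_coupling_index(_raw(a, channels=chans))
        sci_b, _ = scalp_coupling_index(_raw(b, channels=chans))
        assert sci_a[0] == pytest.approx(sci_b[0], abs=1e-9)


class TestOpticalDensity:
    def test_od_zero_for_constant_intensity(self):
        od = od_from_intensity(_raw(np.full((2, 2, 100), 50.0),
                                    channels=_channels(1, 1)))
        np.testing.assert_allclose(od.data, 0.0, atol=1e-14)

    def test_first_baseline_mode_uses_initial_segment(self):
        intens = np.full((1, 2, 200), 100.0)
        intens[:, :, 100:] = 50.0
        od = od_from_intensity(_raw(intens, channels=_channels(0, 1)),
                               i0_mode="first_baseline",
                               baseline_duration=10.0)
        np.testing.assert_allclose(od.data[0, :, :100], 0.0, atol=1e-14)
        np.testing.assert_allclose(od.data[0, :, 100:],
                                   np.log10(2.0), atol=1e-12)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            od_from_intensity(_raw(np.zeros((1, 2, 50)),
                                   channels=_channels(0, 1)))


class TestMotionCorrect:
    def _smooth_signal(self, n=2600, rate=10.0):
        hrf = double_gamma_hrf(rate, 9.0)
        train = np.zeros(n)
        train[::300] = 1.0
        x = fftconvolve(train, hrf)[:n]
        t = np.arange(n) / rate
        return 0.01 * x + 0.002 * np.sin(2 * np.pi * 0.1 * t)

    def test_artifact_free_signal_preserved(self):
        x = self._smooth_signal()
        od = _od(x.reshape(1, 1, -1), channels=_channels(1, 0))
        out = motion_correct(od).data[0, 0]
        assert np.corrcoef(x, out)[0, 1] > 0.99

    def test_step_shift_levelled(self):
        x = self._smooth_signal()
        sd = x.std()
        bad = x.copy()
        bad[1300:] += 10.0 * sd
        od = _od(np.stack([bad, bad]).reshape(1, 2, -1),
                 channels=_channels(1, 0))
        out = motion_correct(od).data[0, 0]
        step_before = abs(bad[1350:1500].mean() - bad[1100:1250].mean())
        step_after = abs(out[1350:1500].mean() - out[1100:1250].mean())
        assert step_after < 0.1 * step_before

    def test_spike_suppressed(self):
        x = self._smooth_signal()
        sd = x.std()
        bad = x.copy()
        bad[1000] += 20.0 * sd
        od = _od(np.stack([bad, bad]).reshape(1, 2, -1),
                 channels=_channels(1, 0))
        out = motion_correct(od).data[0, 0]
        spike_before = abs(bad[1000] - x[1000])
        spike_after = abs(out[1000] - x[1000])
        assert spike_after < 0.1 * spike_before


class TestLowpass:
    def _gain(self, freq, rate=10.0, seconds=600.0):
        t = np.arange(int(rate * seconds)) / rate
        x = np.sin(2 * np.pi * freq * t)
        y = lowpass_physiological(x, rate=rate)
        mid = slice(len(t) // 4, -len(t) // 4)
        return y[mid].std() / x[mid].std()

    def test_dc_unchanged(self):
        y = lowpass_physiological(np.full(3000, 4.0), rate=10.0)
        np.testing.assert_allclose(y, 4.0, rtol=1e-6)

    def test_cardiac_attenuated_20db(self):
        assert self._gain(1.2) < 10 ** (-20 / 20)

    def test_slow_oscillation_preserved(self):
        assert 0.95 <= self._gain(0.01) <= 1.05

    def test_respiratory_attenuated_at_stopband_edge(self):
        assert self._gain(0.25) < 10 ** (-20 / 20)

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            lowpass_physiological(np.zeros(100), rate=10.0)


class TestMBLL:
    def test_zero_od_maps_to_zero_concentration(self):
        od = _od(np.zeros((2, 2, 50)), channels=_channels(2, 0))
        hemo = mbll(od)
        np.testing.assert_allclose(hemo.hbo, 0.0)
        np.testing.assert_allclose(hemo.hbr, 0.0)

    def test_hand_built_two_by_two_system(self):
        # epsilon = [[1,2],[3,1]], L*DPF = 1, dOD = (5,5)
        # -> concentrations (1, 2) mM = (1000, 2000) µM by hand solve
        params = MBLLParams(
            extinction={760.0: {"hbo": 1.0, "hbr": 2.0},
                        850.0: {"hbo": 3.0, "hbr": 1.0}},
            dpf=1.0)
        ch = dataclasses.replace(_channels(1, 0)[0], separation_mm=10.0)
        od = _od(np.full((1, 2, 4), 5.0), channels=[ch])
        hemo = mbll(od, params)
        np.testing.assert_allclose(hemo.hbo[0], 1000.0, rtol=1e-12)
        np.testing.assert_allclose(hemo.hbr[0], 2000.0, rtol=1e-12)

    def test_linearity_doubling_od_doubles_concentrations(self, rng):
        data = rng.standard_normal((2, 2, 100)) * 1e-3
        chans = _channels(2, 0)
        h1 = mbll(_od(data, channels=chans))
        h2 = mbll(_od(2.0 * data, channels=chans))
        np.testing.assert_allclose(2.0 * h1.hbo, h2.hbo, rtol=1e-12)
        np.testing.assert_allclose(2.0 * h1.hbr, h2.hbr, rtol=1e-12)

    def test_singular_extinction_matrix_rejected(self):
        params = MBLLParams(
            extinction={760.0: {"hbo": 1.0, "hbr": 2.0},
                        850.0: {"hbo": 1.0, "hbr": 2.0}},
            dpf=6.0)
        od = _od(np.zeros((1, 2, 10)), channels=_channels(1, 0))
        with pytest.raises(ValueError):
            mbll(od, params)


def _hemo(hbo, channels, rate=10.0):
    hbo = np.asarray(hbo, float)
    return HemoTimeSeries(hbo=hbo, hbr=-hbo / 3.0, rate=rate,
                          channels=channels)


class TestShortChannelRegression:
    def _pair(self):
        longs = _channels(1, 0)
        shorts = [c for c in montage.fnirs_channels() if c.is_short][:1]
        return longs, shorts

    def test_perfectly_scaled_short_removed(self, rng):
        longs, shorts = self._pair()
        s = rng.standard_normal(500)
        out = short_channel_regression(
            _hemo(0.8 * s[None, :], longs), _hemo(s[None, :], shorts))
        assert np.linalg.norm(out.hbo[0]) \
            < 1e-9 * np.linalg.norm(0.8 * s)
        assert out.short_regressed

    def test_orthogonal_neural_component_recovered(self):
        n = 1000
        t = np.arange(n) / 10.0
        neural = np.sin(2 * np.pi * 0.03 * t)
        skin = np.cos(2 * np.pi * 0.05 * t)
        longs, shorts = self._pair()
        out = short_channel_regression(
            _hemo((neural + 0.8 * skin)[None, :], longs),
            _hemo(skin[None, :], shorts))
        assert np.corrcoef(out.hbo[0], neural)[0, 1] > 0.99

    def test_uncorrelated_short_leaves_signal_unchanged(self, rng):
        longs, shorts = self._pair()
        y = rng.standard_normal(2000)
        s = rng.standard_normal(2000)
        out = short_channel_regression(_hemo(y[None, :], longs),
                                       _hemo(s[None, :], shorts))
        # OLS coefficient ~0: output close to the mean-centred input
        assert np.corrcoef(out.hbo[0], y)[0, 1] > 0.99

    def test_residual_variance_never_exceeds_intercept_only(self, rng):
        longs, shorts = self._pair()
        y = rng.standard_normal(500)
        s = 0.3 * y + rng.standard_normal(500)
        out = short_channel_regression(_hemo(y[None, :], longs),
                                       _hemo(s[None, :], shorts))
        assert out.hbo[0].var() <= np.var(y - y.mean()) + 1e-12

    def test_all_short_invalid_passes_through_with_warning(self, rng):
        from pocketlab.eeg_pipeline import ChannelMask
        longs, shorts = self._pair()
        y = rng.standard_normal(300)
        mask = ChannelMask(valid=np.array([False]), reasons=["SCI 0.1"])
        out = short_channel_regression(
            _hemo(y[None, :], longs),
            _hemo(rng.standard_normal(300)[None, :], shorts),
            short_mask=mask)
        np.testing.assert_array_equal(out.hbo[0], y)
        assert out.regression_warning is not None
        assert not out.short_regressed


class TestEpochHbo:
    def test_constant_signal_epochs_to_zero(self):
        chans = _channels(1, 0)
        hemo = _hemo(np.full((1, 800), 3.0), chans)
        res = epoch_hbo(hemo, [StimulusEvent(30.0, TARGET, 0)])
        np.testing.assert_allclose(res.per_class[TARGET].mean, 0.0,
                                   atol=1e-14)

    def test_211_samples_per_epoch_at_10hz(self):
        chans = _channels(1, 0)
        hemo = _hemo(np.zeros((1, 800)), chans)
        res = epoch_hbo(hemo, [StimulusEvent(30.0, TARGET, 0)])
        assert res.per_class[TARGET].mean.shape == (1, 211)
        assert res.times[0] == pytest.approx(-1.0)
        assert res.times[-1] == pytest.approx(20.0)

    def test_event_near_recording_end_dropped(self):
        chans = _channels(1, 0)
        hemo = _hemo(np.zeros((1, 300)), chans)
        res = epoch_hbo(hemo, [StimulusEvent(5.0, TARGET, 0),
                               StimulusEvent(25.0, STANDARD, 1)])
        assert res.n_dropped_edge == 1
        assert STANDARD not in res.per_class

    def test_injected_hrf_peak_time_recovered(self):
        rate = 10.0
        n = 1200
        hrf = double_gamma_hrf(rate, 9.0)
        events = [StimulusEvent(30.0 + 40.0 * k, TARGET, k)
                  for k in range(2)]
        train = np.zeros(n)
        for e in events:
            train[int(e.onset * rate)] = 0.2
        sig = fftconvolve(train, hrf)[:n]
        chans = _channels(1, 0)
        res = epoch_hbo(_hemo(sig[None, :], chans), events)
        assert res.per_class[TARGET].peak_time[0] == pytest.approx(
            9.0, abs=1.0)
        assert res.per_class[TARGET].peak_value[0] == pytest.approx(
            0.2, rel=0.05)
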