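"""SO detection: filtering, criteria, artifact masks, outlier screening."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from sostim.detection import (EEGRecording, SODetectionParams, SOEvent,
                              brunner_mask, detect_sos, filter_slow,
                              outlier_screen, wang_mask)


def make_rec(x, fs=128.0, stage="SWS", name="C3"):
    x = np.atleast_2d(np.asarray(x, float))
    n_epochs = int(np.ceil(x.shape[1] / (30 * fs)))
    return EEGRecording(signals=x, fs=fs,
                        channel_names=[name] if x.shape[0] == 1
                        else [f"ch{i}" for i in range(x.shape[0])],
                        hypnogram=[stage] * n_epochs)


def planted_so(fs=128.0, duration=120.0, t0=60.0, trough=-100.0, peak=40.0,
               neg_s=0.5, pos_s=0.5):
    """One biphasic SO (negative then positive half-sine) on a flat channel."""
    n = int(duration * fs)
    x = np.zeros(n)
    n_neg, n_pos = int(neg_s * fs), int(pos_s * fs)
    i0 = int(t0 * fs)
    x[i0:i0 + n_neg] = trough * np.sin(np.pi * np.arange(n_neg) / n_neg)
    x[i0 + n_neg:i0 + n_neg + n_pos] = peak * np.sin(np.pi * np.arange(n_pos) / n_pos)
    trough_t = (i0 + np.argmin(x[i0:i0 + n_neg])) / fs
    return x, trough_t


class TestFilter:
    def test_dc_is_removed(self):
        rec = make_rec(np.full(128 * 60, 50.0))
        out = filter_slow(rec, (0.1, 4.0))
        assert np.abs(out.signals[:, 128 * 10:-128 * 10]).max() < 1e-6

    @pytest.mark.parametrize("freq,band_check", [(1.0, "pass"), (30.0, "stop")])
    def test_band_edges_match_analytic_response(self, freq, band_check):
        fs, dur = 128.0, 120.0
        t = np.arange(int(fs * dur)) / fs
        rec = make_rec(np.sin(2 * np.pi * freq * t))
        out = filter_slow(rec, (0.1, 4.0))
        mid = out.signals[0, int(20 * fs):int(100 * fs)]
        amp = np.abs(mid).max()
        # oracle: squared magnitude response of the forward-backward filter
        sos = sp_signal.butter(4, (0.1, 4.0), btype="bandpass", output="sos", fs=fs)
        _, h = sp_signal.sosfreqz(sos, worN=[freq], fs=fs)
        expected = np.abs(h[0]) ** 2  # filtfilt applies the filter twice
        if band_check == "pass":
            assert amp == pytest.approx(expected, rel=0.1)
            assert amp > 0.9
        else:
            assert amp < 0.05

    def test_band_outside_nyquist_rejected(self):
        rec = make_rec(np.zeros(1280))
        with pytest.raises(ValueError):
            filter_slow(rec, (0.1, 100.0))


class TestCriteria:
    def test_planted_so_detected_at_trough(self):
        x, trough_t = planted_so()
        rec = make_rec(x)
        events = detect_sos(rec, stage="SWS")
        assert len(events) == 1
        ev = events[0]
        assert abs(ev.t_trough - trough_t) <= 1.5 / rec.fs
        assert ev.trough_amp <= -80
        assert ev.range_amp >= 80
        assert 0.3 <= ev.t_mid - ev.t_start <= 1.0
        assert ev.t_end - ev.t_start <= 10

    def test_shallow_trough_rejected(self):
        x, _ = planted_so(trough=-60.0)
        assert detect_sos(make_rec(x), stage="SWS") == []

    def test_short_half_wave_rejected(self):
        x, _ = planted_so(neg_s=0.2, pos_s=0.2)
        assert detect_sos(make_rec(x), stage="SWS") == []

    def test_long_half_wave_rejected(self):
        x, _ = planted_so(neg_s=1.4, pos_s=0.5)
        assert detect_sos(make_rec(x), stage="SWS") == []

    def test_wrong_stage_excluded(self):
        x, _ = planted_so()
        rec = make_rec(x, stage="REM")
        assert detect_sos(rec, stage="SWS") == []
        assert len(detect_sos(rec, stage="REM")) == 1

    def test_unknown_stage_errors(self):
        x, _ = planted_so()
        with pytest.raises(ValueError):
            detect_sos(make_rec(x), stage="N2")

    def test_scorer_excluded_epoch_discards_event(self):
        x, trough_t = planted_so()
        rec = make_rec(x)
        rec.excluded_epochs[int(trough_t // 30)] = True
        assert detect_sos(rec, stage="SWS") == []

    def test_translation_equivariance(self):
        x, _ = planted_so(duration=180.0, t0=70.0)
        shift = 256  # 2 s
        rec_a = make_rec(x)
        rec_b = make_rec(np.roll(x, shift))
        ev_a = detect_sos(rec_a, stage="SWS")
        ev_b = detect_sos(rec_b, stage="SWS")
        assert len(ev_a) == len(ev_b) == 1
        assert ev_b[0].t_trough - ev_a[0].t_trough == pytest.approx(
            shift / rec_a.fs, abs=1.5 / rec_a.fs)

    def test_empty_recording_returns_empty(self):
        rec = make_rec(np.zeros(1))
        assert detect_sos(rec, stage="SWS") == []

    def test_event_time_ordering_invariant(self):
        with pytest.raises(ValueError):
            SOEvent(channel="C3", t_start=1.0, t_mid=0.5, t_end=2.0,
                    t_trough=1.2, trough_amp=-90, range_amp=100, stage="SWS")


class TestMasks:
    def test_pure_slow_signal_unflagged(self):
        t = np.arange(int(128 * 240)) / 128
        rec = make_rec(50 * np.sin(2 * np.pi * 1.0 * t))
        assert not brunner_mask(rec).any()
        assert not wang_mask(rec).any()

    def test_brunner_flags_high_frequency_burst(self, rng):
        fs, dur = 128.0, 240.0
        t = np.arange(int(fs * dur)) / fs
        base = np.sin(2 * np.pi * 29 * t)  # weak in-band background
        burst = np.zeros_like(t)
        b0 = int(100 * fs)
        burst[b0:b0 + int(4 * fs)] = 10 * np.sin(2 * np.pi * 29 * t[:int(4 * fs)])
        rec = make_rec(base + burst)
        mask = brunner_mask(rec)
        flagged = np.flatnonzero(mask[0])
        assert 25 in flagged  # the burst occupies bin 100/4 = 25
        assert len(flagged) <= 2

    def test_brunner_scale_invariance(self, rng):
        # µV-scale noise, well above the absolute artifact floor
        x = 20 * rng.standard_normal(int(128 * 240))
        x[int(100 * 128):int(104 * 128)] *= 8
        rec1, rec5 = make_rec(x), make_rec(5 * x)
        m1, m5 = brunner_mask(rec1), brunner_mask(rec5)
        assert m1.any()
        np.testing.assert_array_equal(m1, m5)

    def test_wang_flags_high_power_segment(self, rng):
        fs, dur = 128.0, 300.0
        x = rng.standard_normal(int(fs * dur))
        s0 = int(150 * fs)
        x[s0:s0 + int(5 * fs)] *= 10
        rec = make_rec(x)
        mask = wang_mask(rec)
        assert mask[0, 30]  # 150 s / 5 s = bin 30
        assert mask[0].sum() <= 2

    def test_wang_stationary_noise_false_positive_rate(self, rng):
        x = rng.standard_normal((4, int(128 * 300)))
        rec = make_rec(x)
        mask = wang_mask(rec)
        assert mask.mean() < 0.01

    def test_all_zero_record_unflagged(self):
        rec = make_rec(np.zeros(int(128 * 240)))
        assert not brunner_mask(rec).any()
        assert not wang_mask(rec).any()

    def test_masks_idempotent_on_zeroed_record(self):
        rec = make_rec(np.zeros(int(128 * 240)))
        m1 = wang_mask(rec)
        assert not m1.any()


class TestOutlierScreen:
    def _event(self, channel, amp, t):
        return SOEvent(channel=channel, t_start=t, t_mid=t + 0.5, t_end=t + 1.0,
                       t_trough=t + 0.25, trough_amp=-amp, range_amp=2 * amp,
                       stage="SWS", ref_amp=amp)

    def test_identical_amplitudes_all_kept(self):
        events = [self._event("C3", 100.0, 10 + 2 * i) for i in range(100)]
        assert len(outlier_screen(events)) == 100

    def test_extreme_outlier_removed_in_pass1(self, rng):
        events = [self._event("C3", 100 + rng.normal(0, 5), 10 + 2 * i)
                  for i in range(99)]
        events.append(self._event("C3", 10_000.0, 300.0))
        kept = outlier_screen(events)
        assert len(kept) == 99
        assert all(e.ref_amp < 1000 for e in kept)

    def test_single_event_electrode_skips_pass1(self, rng):
        # the lone O1 event survives pass 1 (per-electrode SD undefined)
        # and sits inside the pooled mean + 4 SD band in pass 2
        events = [self._event("O1", 130.0, 5.0)]
        events += [self._event("C3", 100 + rng.normal(0, 10), 10 + 2 * i)
                   for i in range(30)]
        kept = outlier_screen(events)
        assert any(e.channel == "O1" for e in kept)
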