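"""Segmentation, pulse detection, call typing, and short-call features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryptofrog import acoustics as ac
from cryptofrog import synth


def _tone(freq, dur, rate, amp=1.0):
    t = np.arange(int(dur * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


class TestEnvelope:
    def test_zero_input_gives_zero_envelope(self, rate):
        env = ac.envelope(np.zeros(1000), rate)
        assert np.all(env == 0)

    def test_sign_flip_invariance(self, rate):
        x = np.random.default_rng(0).normal(size=4000)
        assert np.allclose(ac.envelope(x, rate), ac.envelope(-x, rate))

    def test_tone_plateau_matches_sine_rms(self, rate):
        # moving RMS of a unit sinusoid is 1/sqrt(2)
        x = _tone(3200.0, 0.1, rate)
        env = ac.envelope(x, rate, smooth_ms=2.0)
        mid = env[len(env) // 4 : 3 * len(env) // 4]
        assert np.allclose(mid, 1 / np.sqrt(2), rtol=0.05)

    def test_empty_input_rejected(self, rate):
        with pytest.raises(ValueError):
            ac.envelope(np.array([]), rate)


class TestSegmentation:
    def test_silence_yields_no_calls(self, rate):
        rec = ac.CallRecording(np.zeros(int(rate)), rate)
        assert ac.segment_calls(rec) == []

    def test_two_short_calls_found_at_known_onsets(self, short_call_pair):
        rec, onsets = short_call_pair
        calls = ac.segment_calls(rec)
        assert len(calls) == 2
        for call, onset in zip(calls, onsets):
            assert call.start_time == pytest.approx(onset, abs=0.005)

    def test_pulsed_long_call_stays_one_unit(self, rate):
        p = synth.CallSynthParams(call_class="long_type1", pulse_count=16,
                                  pulse_rate=20.0, carrier_freq=3300.0,
                                  noise_snr_db=30.0, seed=4)
        wav = synth.synth_call(p, rate)
        sil = np.zeros(int(rate))
        rec = ac.CallRecording(np.concatenate([sil, wav, sil]), rate)
        assert len(ac.segment_calls(rec)) == 1

    def test_segments_ordered_and_non_overlapping(self, short_call_pair):
        rec, _ = short_call_pair
        calls = ac.segment_calls(rec)
        for a, b in zip(calls, calls[1:]):
            assert a.end_time <= b.start_time


class TestPulseDetection:
    def test_single_raised_cosine_pulse_centered(self, rate):
        n = int(0.02 * rate)
        x = np.hanning(n) * _tone(3300.0, 0.02, rate)
        sil = np.zeros(int(0.5 * rate))
        rec = ac.CallRecording(np.concatenate([sil, x, sil]), rate)
        env = ac.envelope(rec.samples, rate)
        call = ac.Call(start_time=0.49, end_time=0.53)
        pulses = ac.detect_pulses(call, env, rate)
        assert len(pulses) == 1
        assert pulses[0].peak_time == pytest.approx(0.5 + 0.01, abs=0.001)

    @pytest.mark.parametrize("n_pulses,pulse_rate,snr", [
        (17, 20.0, 30.0),  # modal pulse count of the study's long calls
        (16, 50.0, 20.0),  # fast train at lower SNR
    ])
    def test_pulse_count_recovered(self, rate, n_pulses, pulse_rate, snr):
        p = synth.CallSynthParams(call_class="long_type1", pulse_count=n_pulses,
                                  pulse_rate=pulse_rate, carrier_freq=3300.0,
                                  noise_snr_db=snr, seed=5)
        wav = synth.synth_call(p, rate)
        sil = np.zeros(int(rate))
        rec = ac.CallRecording(np.concatenate([sil, wav, sil]), rate)
        env = ac.envelope(rec.samples, rate)
        (call,) = ac.segment_calls(rec)
        assert len(ac.detect_pulses(call, env, rate)) == n_pulses

    def test_degenerate_call_rejected(self, rate):
        env = np.ones(100)
        with pytest.raises(ValueError):
            ac.detect_pulses(ac.Call(0.001, 0.001), env, rate)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_pulse_count_invariant_under_amplitude_scaling(self, scale):
        rate = 44100.0
        p = synth.CallSynthParams(call_class="long_type1", pulse_count=12,
                                  pulse_rate=20.0, carrier_freq=3300.0,
                                  noise_snr_db=np.inf, seed=6)
        wav = synth.synth_call(p, rate) * scale
        sil = np.zeros(int(0.5 * rate))
        rec = ac.CallRecording(np.concatenate([sil, wav, sil]), rate)
        env = ac.envelope(rec.samples, rate)
        (call,) = ac.segment_calls(rec)
        assert len(ac.detect_pulses(call, env, rate)) == 12


class TestCallTyping:
    @staticmethod
    def _call_with(n_pulses):
        pulses = [ac.Pulse(peak_time=0.01 * i, peak_amplitude=1.0) for i in range(n_pulses)]
        return ac.Call(0.0, 0.01 * max(n_pulses, 1), pulses=pulses)

    @pytest.mark.parametrize("n_total,expected", [
        (16, ac.LONG),  # the study's typical train
        (1, ac.SHORT),
        (5, ac.LONG),   # 4 pulses after the first rising peak
        (4, ac.SHORT),  # exactly 3 after the first: the rule gap, SHORT
    ])
    def test_long_short_rule(self, n_total, expected):
        assert ac.classify_call(self._call_with(n_total)) == expected

    def test_zero_pulses_is_short_with_flag(self):
        call = self._call_with(0)
        assert ac.classify_call(call) == ac.SHORT
        assert "no_pulses" in call.flags

    def test_flat_train_is_type1(self, rate):
        p = synth.CallSynthParams(call_class="long_type1", pulse_count=16,
                                  pulse_rate=20.0, carrier_freq=3300.0,
                                  noise_snr_db=30.0, seed=7)
        wav = synth.synth_call(p, rate)
        sil = np.zeros(int(rate))
        rec = ac.CallRecording(np.concatenate([sil, wav, sil]), rate)
        env = ac.envelope(rec.samples, rate)
        (call,) = ac.segment_calls(rec)
        call.pulses = ac.detect_pulses(call, env, rate)
        assert ac.classify_long_type(call) == ac.LONG_TYPE1

    def test_onset_peak_with_rising_train_is_type2(self, rate):
        p = synth.CallSynthParams(call_class="long_type2", pulse_count=16,
                                  pulse_rate=20.0, carrier_freq=3300.0,
                                  amplitude_profile="weak_to_strong",
                                  noise_snr_db=30.0, seed=8)
        wav = synth.synth_call(p, rate)
        sil = np.zeros(int(rate))
        rec = ac.CallRecording(np.concatenate([sil, wav, sil]), rate)
        env = ac.envelope(rec.samples, rate)
        (call,) = ac.segment_calls(rec)
        call.pulses = ac.detect_pulses(call, env, rate)
        assert ac.classify_long_type(call) == ac.LONG_TYPE2

    def test_degenerate_flat_train_cv_zero_is_type1(self):
        pulses = [ac.Pulse(0.01 * i, 1.0) for i in range(8)]
        call = ac.Call(0.0, 0.1, pulses=pulses)
        assert ac.classify_long_type(call) == ac.LONG_TYPE1

    def test_fewer_than_four_pulses_rejected(self):
        call = self._call_with(3)
        with pytest.raises(ValueError):
            ac.classify_long_type(call)


class TestShortCallFeatures:
    def test_rectangular_tone_dt_and_df(self, rate):
        # 0.1 s rectangular 3200 Hz tone: DT ~ 0.1 s, DF within one bin
        x = _tone(3200.0, 0.1, rate)
        call = ac.Call(0.0, 0.1)
        f = ac.short_call_features(call, x, rate)
        assert f.DT == pytest.approx(0.1, abs=1e-3)
        assert abs(f.DF - 3200.0) <= rate / 1024

    def test_symmetric_envelope_splits_rise_and_fall(self, rate):
        n = int(0.1 * rate)
        env = 1 - np.abs(np.linspace(-1, 1, n))
        x = env * _tone(3000.0, 0.1, rate)
        f = ac.short_call_features(ac.Call(0.0, 0.1), x, rate)
        assert f.RT == pytest.approx(f.DT / 2, abs=0.005)
        assert f.FT == pytest.approx(f.DT / 2, abs=0.005)

    @pytest.mark.parametrize("freq", [500.0, 1234.0, 3202.7, 3341.5, 5000.0, 7900.0])
    def test_pure_tone_df_within_one_bin(self, rate, freq):
        x = _tone(freq, 0.15, rate)
        f = ac.short_call_features(ac.Call(0.0, 0.15), x, rate)
        assert abs(f.DF - freq) <= rate / 1024

    def test_dt_equals_rt_plus_ft(self, short_call_pair):
        rec, _ = short_call_pair
        for call in ac.segment_calls(rec):
            f = ac.short_call_features(call, rec.samples, rec.rate)
            assert f.DT == pytest.approx(f.RT + f.FT, abs=1.0 / rec.rate)

    def test_subsegment_call_flagged(self, rate):
        x = _tone(3000.0, 0.012, rate)
        call = ac.Call(0.0, 0.012)
        f = ac.short_call_features(call, x, rate)
        assert "short_fft_segment" in call.flags
        assert abs(f.DF - 3000.0) <= rate / 1024


class TestIndividualProfile:
    def test_mean_of_identical_features_is_identity(self):
        f = ac.ShortCallFeatures(0.1, 0.08, 0.02, 3200.0, 50.0)
        prof = ac.individual_profile([f] * 10)
        for field in ("DT", "RT", "FT", "DF", "IQR"):
            assert getattr(prof, field) == pytest.approx(getattr(f, field))

    def test_mean_of_mixed_durations(self):
        feats = [ac.ShortCallFeatures(0.1, 0.05, 0.05, 3000.0, 10.0)] * 5 + \
                [ac.ShortCallFeatures(0.2, 0.10, 0.10, 3000.0, 10.0)] * 5
        assert ac.individual_profile(feats).DT == pytest.approx(0.15)

    def test_fewer_than_ten_calls_excluded(self):
        f = ac.ShortCallFeatures(0.1, 0.08, 0.02, 3200.0, 50.0)
        assert ac.individual_profile([f] * 9) is None

    def test_only_first_ten_calls_enter_the_mean(self):
        feats = [ac.ShortCallFeatures(0.1, 0.05, 0.05, 3000.0, 10.0)] * 10 + \
                [ac.ShortCallFeatures(9.9, 0.05, 0.05, 3000.0, 10.0)] * 5
        assert ac.individual_profile(feats).DT == pytest.approx(0.1)
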