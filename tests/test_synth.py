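"""The synthetic-data generators and their round-trip guarantees."""

import numpy as np
import pytest

from cryptofrog import acoustics as ac
from cryptofrog import moldist, synth


class TestSynthCall:
    def test_zero_amplitude_gives_silence_of_correct_length(self, rate):
        p = synth.CallSynthParams(call_class="short", dt_target=0.1,
                                  rt_target=0.08, ft_target=0.02,
                                  amplitude=0.0, seed=0)
        wav = synth.synth_call(p, rate)
        assert wav.size == pytest.approx(0.1 * rate, abs=3)
        assert np.all(wav == 0)

    def test_type2_envelope_has_onset_peak_and_rising_trend(self):
        times, amps = synth._pulse_times_amps(
            synth.CallSynthParams(call_class="long_type2", pulse_count=16,
                                  pulse_rate=20.0, onset_peak_gain=2.0,
                                  amplitude_profile="weak_to_strong"))
        mid = amps[1:-1]
        assert amps[0] >= 1.5 * np.median(mid)
        assert np.all(np.diff(mid) > 0)
        # accelerating train: inter-pulse gaps shrink
        assert np.all(np.diff(np.diff(times)) < 1e-12)

    def test_carrier_above_nyquist_rejected(self):
        p = synth.CallSynthParams(call_class="short", carrier_freq=30000.0,
                                  dt_target=0.1, rt_target=0.08, ft_target=0.02)
        with pytest.raises(ValueError, match="Nyquist"):
            synth.synth_call(p, 44100.0)

    def test_inconsistent_durations_rejected(self):
        with pytest.raises(ValueError):
            synth.synth_call(synth.CallSynthParams(
                call_class="short", dt_target=0.1, rt_target=0.08, ft_target=0.08))

    def test_deterministic_given_seed(self, rate):
        p = synth.CallSynthParams(call_class="long_type1", pulse_count=16, seed=9)
        assert np.array_equal(synth.synth_call(p, rate), synth.synth_call(p, rate))

    def test_long_type1_pulse_count_round_trip(self, rate):
        p = synth.CallSynthParams(call_class="long_type1", pulse_count=16,
                                  pulse_rate=20.0, noise_snr_db=30.0, seed=10)
        wav = synth.synth_call(p, rate)
        sil = np.zeros(int(rate))
        rec = ac.CallRecording(np.concatenate([sil, wav, sil]), rate)
        env = ac.envelope(rec.samples, rate)
        (call,) = ac.segment_calls(rec)
        assert len(ac.detect_pulses(call, env, rate)) == 16

    def test_short_call_dt_and_df_round_trip(self, rate):
        p = synth.CallSynthParams(call_class="short", carrier_freq=3202.7,
                                  dt_target=0.1127, rt_target=0.0882,
                                  ft_target=0.0245, noise_snr_db=30.0, seed=11)
        wav = synth.synth_call(p, rate)
        sil = np.zeros(int(rate))
        samples = np.concatenate([sil, wav, sil])
        rng = np.random.default_rng(12)
        samples = samples + rng.normal(0, np.sqrt(np.mean(wav**2)) / 31.6, samples.size)
        rec = ac.CallRecording(samples, rate)
        (call,) = ac.segment_calls(rec)
        f = ac.short_call_features(call, rec.samples, rate)
        assert f.DT == pytest.approx(0.1127, rel=0.10)
        assert abs(f.DF - 3202.7) <= rate / 1024


class TestPopulationRecordings:
    def test_jp_profile_emits_only_type1a(self):
        s = synth.synth_population_recordings(synth.JP_PROFILE, 8, seed=1)
        long_calls = s.calls[s.calls.true_class != "short"]
        assert set(long_calls.true_long_type) == {"Type1A"}

    def test_ot_profile_emits_type2_never_type1a(self):
        s = synth.synth_population_recordings(synth.OT_PROFILE, 20, seed=2)
        long_calls = s.calls[s.calls.true_class != "short"]
        assert "Type2" in set(long_calls.true_long_type)
        assert "Type1A" not in set(long_calls.true_long_type)

    def test_same_seed_is_byte_identical(self):
        a = synth.synth_population_recordings(synth.OT_PROFILE, 3, seed=5)
        b = synth.synth_population_recordings(synth.OT_PROFILE, 3, seed=5)
        assert all(np.array_equal(x.samples, y.samples)
                   for x, y in zip(a.recordings, b.recordings))
        assert a.individuals.equals(b.individuals)

    def test_rejects_too_few_calls(self):
        with pytest.raises(ValueError):
            synth.synth_population_recordings(synth.JP_PROFILE, 2,
                                              calls_per_individual=5)


class TestSynthSequences:
    def test_zero_targets_give_identical_sequences(self):
        params = synth.SeqSimParams(
            seq_length=100, group_sizes={"a": 3, "b": 3},
            within_targets={"a": 0.0, "b": 0.0},
            between_targets={frozenset({"a", "b"}): 0.0}, seed=0)
        seqs = synth.synth_sequences(params)
        assert len({s.bases for s in seqs}) == 1

    def test_two_group_between_target_recovered(self):
        params = synth.SeqSimParams(
            seq_length=1016, group_sizes={"a": 10, "b": 10},
            within_targets={"a": 0.005, "b": 0.005},
            between_targets={frozenset({"a", "b"}): 0.16}, seed=1)
        seqs = synth.synth_sequences(params)
        tab = moldist.group_divergence(seqs)
        assert 0.15 <= tab.between[frozenset({"a", "b"})] <= 0.17

    @pytest.mark.parametrize("seed", range(5))
    def test_six_lineage_recovery_across_seeds(self, seed):
        params = synth.study_divergence_params(seed=seed, scale_n=0.3)
        seqs = synth.synth_sequences(params)
        tab = moldist.group_divergence(seqs)
        for pair, target in params.between_targets.items():
            assert tab.between[pair] == pytest.approx(target, abs=0.01)

    def test_infeasible_targets_rejected(self):
        params = synth.SeqSimParams(
            seq_length=1016, group_sizes={"a": 5, "b": 5},
            within_targets={"a": 0.2, "b": 0.2},
            between_targets={frozenset({"a", "b"}): 0.01}, seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            synth.synth_sequences(params)

    def test_sequence_length_budget_enforced(self):
        params = synth.SeqSimParams(
            seq_length=50, group_sizes={"a": 30, "b": 30},
            within_targets={"a": 0.2, "b": 0.2},
            between_targets={frozenset({"a", "b"}): 0.5}, seed=0)
        with pytest.raises(ValueError):
            synth.synth_sequences(params)


class TestSynthMorphometrics:
    def test_clade_head_difference_planted(self):
        df = synth.synth_morphometrics(seed=0)
        hl = df.groupby("clade").apply(
            lambda g: (g["HL"] / g["SVL"]).mean(), include_groups=False)
        assert hl["OT"] > hl["JP"]

    def test_deterministic(self):
        assert synth.synth_morphometrics(seed=3).equals(
            synth.synth_morphometrics(seed=3))


class TestSynthPlayback:
    def test_require_valid_returns_only_valid_trials(self):
        from cryptofrog import playback
        trials = synth.synth_playback_trials("OT", 13, require_valid=True, seed=0)
        assert len(trials) == 13
        assert all(playback.trial_valid(t) for t in trials)

    def test_poisson_mode_has_no_gamma_mixing(self):
        a = synth.synth_playback_trials("OT", 50, dispersion=None, seed=1)
        counts = np.array([t.response_counts["Type2"] for t in a])
        # Poisson: variance ~ mean (NB with k=1 would be ~mean + mean^2)
        assert counts.var() < 2.5 * counts.mean()
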