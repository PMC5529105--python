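import numpy as np
import pytest

from pavcond import spikes, synth
from pavcond.session import LR_REWARD_DELAY, SR_REWARD_DELAY


class TestGenerateTrials:
    def test_two_hundred_trials_balanced(self):
        trials = synth.generate_trials(200, rng_seed=1)
        assert len(trials) == 200
        n_lr = sum(t.condition == "LR" for t in trials)
        assert abs(n_lr - (200 - n_lr)) <= 1

    def test_block_of_two_balance(self):
        trials = synth.generate_trials(2, rng_seed=5)
        assert {t.condition for t in trials} == {"LR", "SR"}

    def test_deterministic(self):
        a = synth.generate_trials(50, rng_seed=9)
        b = synth.generate_trials(50, rng_seed=9)
        assert a == b

    def test_rejects_zero_trials(self):
        with pytest.raises(ValueError):
            synth.generate_trials(0)

    def test_timing_rules(self):
        trials = synth.generate_trials(100, rng_seed=3)
        for t in trials:
            fix = t.cs_onset - t.fp_onset
            assert 0.7 <= fix <= 1.2
            if t.condition == "LR":
                assert t.reward_time == pytest.approx(t.cs_onset + LR_REWARD_DELAY, abs=1e-5)
            else:
                assert t.reward_time == pytest.approx(t.cs_offset + SR_REWARD_DELAY, abs=1e-5)

    def test_inactivation_epochs(self):
        trials = synth.generate_trials(100, rng_seed=0, inactivation=True)
        epochs = [t.epoch for t in trials]
        assert epochs[:60] == ["pre_inactivation"] * 60
        assert epochs[60:] == ["during_inactivation"] * 40


class TestGenerateSpikeTrain:
    def test_homogeneous_limit(self):
        trials = synth.generate_trials(10, rng_seed=0)
        params = synth.NeuronParams.da(
            fp_delta=0, cs_delta_lr=0, cs_delta_sr=0,
            rw_delta_predicted=0, rw_delta_unpredicted=0,
        )
        st = synth.generate_spike_train(trials, params, rng_seed=7, t_end=1000.0)
        # Poisson(5000): 5 SD band
        assert abs(len(st) - 5000) < 5 * np.sqrt(5000)

    def test_cs_window_mean_rate_matches_closed_form(self, fast_trial_config):
        trials = synth.generate_trials(400, fast_trial_config, rng_seed=2)
        params = synth.NeuronParams.da(
            baseline_rate=5.0, cs_delta_lr=25.0,
            response_latency=100.0, response_duration=200.0,
        )
        st = synth.generate_spike_train(trials, params, rng_seed=11)
        rates = spikes.window_rate(st, trials, "CS", (0.1, 0.3), condition="LR")
        # closed form: baseline + delta = 30 Hz; allow 3 SE
        se = np.sqrt(30.0 / 0.2) / np.sqrt(rates.size)
        assert rates.mean() == pytest.approx(30.0, abs=3 * se)

    def test_deterministic(self, fast_trial_config):
        trials = synth.generate_trials(20, fast_trial_config, rng_seed=0)
        a = synth.generate_spike_train(trials, synth.NeuronParams.da(), rng_seed=4)
        b = synth.generate_spike_train(trials, synth.NeuronParams.da(), rng_seed=4)
        assert a == b

    def test_strictly_increasing(self, fast_trial_config):
        trials = synth.generate_trials(50, fast_trial_config, rng_seed=0)
        st = synth.generate_spike_train(trials, synth.NeuronParams.snr(), rng_seed=1)
        assert np.all(np.diff(st.spike_times) > 0)

    def test_empty_trial_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            synth.generate_spike_train(synth.TrialTable(), synth.NeuronParams.da())

    def test_inactivation_suppresses_cs_not_rw(self, fast_trial_config):
        trials = synth.generate_trials(300, fast_trial_config, rng_seed=1,
                                       inactivation=True)
        params = synth.NeuronParams.da(cs_delta_lr=30.0, rw_delta_predicted=0.0,
                                       rw_delta_unpredicted=30.0,
                                       response_latency=100.0)
        st = synth.generate_spike_train(
            trials, params, rng_seed=3, mode=synth.InactivationMode.abolish()
        )
        pre = trials.select(epoch="pre_inactivation")
        dur = trials.select(epoch="during_inactivation")
        cs_pre = spikes.window_rate(st, pre, "CS", (0.1, 0.3), "LR").mean()
        cs_dur = spikes.window_rate(st, dur, "CS", (0.1, 0.3), "LR").mean()
        rw_dur = spikes.window_rate(st, dur, "RW", (0.1, 0.3), "LR").mean()
        assert cs_pre > 20.0  # ~35 Hz programmed
        assert cs_dur < 15.0  # CS bump scaled to zero
        assert rw_dur > 20.0  # unmasked reward response


class TestGenerateLicks:
    def test_lr_anticipation_exceeds_sr(self, trials_200):
        licks = synth.generate_licks(trials_200, rng_seed=0)
        from pavcond import behavior

        lr = behavior.cr_rate(licks, trials_200, "LR", (0.0, 1.3))
        sr = behavior.cr_rate(licks, trials_200, "SR", (0.0, 1.3))
        assert lr > sr

    def test_abolished_anticipation_no_lr_sr_difference(self, fast_trial_config):
        trials = synth.generate_trials(400, fast_trial_config, rng_seed=3)
        licks = synth.generate_licks(
            trials, mode=synth.InactivationMode.abolish(), rng_seed=0
        )
        from pavcond import behavior

        lr = behavior.cr_rate(licks, trials, "LR", (0.0, 0.7))
        sr = behavior.cr_rate(licks, trials, "SR", (0.0, 0.7))
        assert lr == pytest.approx(sr, abs=0.35)

    def test_reward_only_licking(self, trials_200):
        params = synth.BehaviorParams(
            lick_baseline=0.0, lick_anticipatory_lr=0.0,
            lick_anticipatory_sr=0.0, lick_post_reward=6.0,
        )
        licks = synth.generate_licks(trials_200, params, rng_seed=2)
        assert len(licks) > 0
        reward_windows = [
            (t.reward_time, t.reward_time + 1.0)
            for t in trials_200 if t.reward_time is not None
        ]
        for x in licks.lick_times:
            assert any(lo <= x < hi + 1e-9 for lo, hi in reward_windows)

    def test_refractory_period(self, trials_200):
        licks = synth.generate_licks(trials_200, rng_seed=5)
        assert np.all(np.diff(licks.lick_times) >= 0.08 - 1e-9)


class TestGenerateWaveform:
    def test_programmed_width_recovered(self):
        for width in (0.6, 0.25):
            params = synth.NeuronParams.da(waveform_width=width)
            wf = synth.generate_waveform(params, rng_seed=0, noise_sd=0.0)
            assert spikes.spike_width(wf) == pytest.approx(width, abs=0.0126)

    def test_noiseless_is_deterministic_across_seeds(self):
        a = synth.generate_waveform(synth.NeuronParams.da(), rng_seed=1, noise_sd=0.0)
        b = synth.generate_waveform(synth.NeuronParams.da(), rng_seed=2, noise_sd=0.0)
        assert np.array_equal(a.samples, b.samples)

    def test_unrepresentable_width(self):
        params = synth.NeuronParams.da(waveform_width=0.04)
        with pytest.raises(ValueError, match="not representable"):
            synth.generate_waveform(params, sample_interval_ms=0.025)


class TestGeneratePsychometricTrials:
    def test_fraction_correct_at_threshold(self):
        loc = (10.0, 45.0)
        params = synth.PsychoParams(thresholds={loc: 0.3})
        rec = synth.generate_psychometric_trials(params, 20000, [0.3], rng_seed=0)
        # correct endpoints land on the target (x > 0), incorrect at the antipode
        frac = np.mean([t.saccade_endpoint[0] > 0 for t in rec])
        # criterion probability at d'=2 under the default model
        assert frac == pytest.approx(0.8413, abs=0.01)

    def test_asymptotes(self):
        loc = (10.0, 45.0)
        params = synth.PsychoParams(thresholds={loc: 0.3}, slope=8.0, guess_rate=0.1)
        hi = synth.generate_psychometric_trials(params, 2000, [0.9], rng_seed=1)
        frac_hi = np.mean([t.saccade_endpoint[0] > 0 for t in hi])
        assert frac_hi > 0.99
        lo = synth.generate_psychometric_trials(params, 2000, [0.011], rng_seed=2)
        frac_lo = np.mean([t.saccade_endpoint[0] > 0 for t in lo])
        assert frac_lo == pytest.approx(0.1, abs=0.03)


class TestReversalDataset:
    def test_instant_learning_reverses_on_switch_day(self):
        sessions, truth = synth.generate_reversal_dataset(
            6, [4], learning_rate=1.0, rng_seed=0, n_trials=60
        )
        assert truth["days"][2]["w_upper_lr"] == 1.0
        assert truth["days"][3]["w_upper_lr"] == 0.0

    def test_no_learning_never_crosses(self):
        _sessions, truth = synth.generate_reversal_dataset(
            6, [3], learning_rate=0.0, rng_seed=0, n_trials=60
        )
        assert all(d["w_upper_lr"] == 1.0 for d in truth["days"])

    def test_half_rate_crossing_between_day_10_and_13(self):
        # w relaxes from 1 toward 0 at rate 0.5 from day 10:
        # day 10 -> 0.5 (tie), day 11 -> 0.25 (crossed)
        _sessions, truth = synth.generate_reversal_dataset(
            14, [10], learning_rate=0.5, rng_seed=0, n_trials=40
        )
        w = {d["day"]: d["w_upper_lr"] for d in truth["days"]}
        assert w[9] == 1.0
        assert w[10] == pytest.approx(0.5)
        assert w[11] == pytest.approx(0.25)
        crossing_day = next(d for d in range(10, 15) if w[d] < 0.5)
        assert 10 < crossing_day <= 13

    def test_switch_day_bounds_checked(self):
        with pytest.raises(ValueError):
            synth.generate_reversal_dataset(5, [9], 0.5)


class TestInactivationMode:
    def test_none_mode_must_be_neutral(self):
        with pytest.raises(ValueError):
            synth.InactivationMode(mode="none", cs_response_scale=0.5)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            synth.InactivationMode(mode="whatever")


def test_truth_emitted_with_session():
    cfg = synth.SessionConfig(n_trials=20, n_da=1, n_snr=1)
    _session, truth = synth.generate_session(cfg, rng_seed=3)
    assert set(truth["neurons"]) == {"da00", "snr00"}
    assert 60.0 <= truth["neurons"]["da00"]["response_latency"] <= 160.0
    assert truth["behavior"]["lick_anticipatory_lr"] == 4.0


def test_generators_bit_reproducible():
    cfg = synth.SessionConfig(n_trials=30, n_da=1, n_snr=1)
    a, ta = synth.generate_session(cfg, rng_seed=99)
    b, tb = synth.generate_session(cfg, rng_seed=99)
    assert a.trials == b.trials and a.licks == b.licks and a.spikes == b.spikes
    assert ta == tb
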