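import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pavcond import synth
from pavcond.session import SpikeTrain, Trial, TrialTable, WaveformTemplate
from pavcond.spikes import (
    baseline_stats,
    classify_neuron,
    compare_window_rates,
    discrimination_onset,
    exact_sign_test,
    psth,
    response_latency,
    sign_test_p,
    spike_width,
    waveform_stability,
    window_rate,
)


def _single_trial(cs_onset=10.0):
    return TrialTable([
        Trial(
            trial_id=0, condition="LR", fp_onset=cs_onset - 1.0,
            cs_onset=cs_onset, cs_offset=cs_onset + 1.7,
            reward_time=cs_onset + 1.3, reward_volume=0.17,
            cs_position=(10.0, 45.0),
        )
    ])


class TestSpikeWidth:
    def test_hand_built_trough_and_peak(self):
        # trough at sample 10, peak at sample 34, 0.025 ms sampling -> 0.600 ms
        x = np.zeros(48)
        x[5:11] = -np.linspace(0.1, 1.0, 6)
        x[11:16] = -np.linspace(0.8, 0.1, 5)
        x[28:35] = np.linspace(0.1, 0.7, 7)
        x[35:41] = np.linspace(0.6, 0.1, 6)
        wf = WaveformTemplate(x, 0.025)
        assert spike_width(wf) == pytest.approx(0.600, abs=1e-9)

    def test_monotone_ramp_unmeasurable(self):
        wf = WaveformTemplate(np.linspace(-1, 1, 40), 0.025)
        with pytest.raises(ValueError, match="unmeasurable"):
            spike_width(wf)

    def test_generator_contract(self):
        for width in (0.5, 0.6, 0.75):
            wf = synth.generate_waveform(
                synth.NeuronParams.da(waveform_width=width), noise_sd=0.0
            )
            assert spike_width(wf) == pytest.approx(width, abs=0.0126)


class TestClassifyNeuron:
    @pytest.mark.parametrize(
        "rate,width,label",
        [
            (5.0, 0.6, "DA"),
            (60.0, 0.25, "SNr"),
            (25.0, 0.6, "unclassified"),
            (5.0, 0.3, "unclassified"),
            (1.0, 0.46, "DA"),     # boundary: rate range inclusive
            (10.0, 0.45, "unclassified"),  # width must exceed 0.45
            (40.0, 0.25, "unclassified"),  # SNr needs rate strictly above 40
        ],
    )
    def test_rule(self, rate, width, label):
        assert classify_neuron(rate, width).label == label


class TestBaselineStats:
    def test_deterministic_one_spike_per_bin(self):
        trials = []
        spike_times = []
        for i in range(12):
            fp = 10.0 + 10.0 * i
            trials.append(
                Trial(
                    trial_id=i, condition="LR", fp_onset=fp, cs_onset=fp + 1.0,
                    cs_offset=fp + 2.7, reward_time=fp + 2.3, reward_volume=0.17,
                    cs_position=(10.0, 45.0),
                )
            )
            spike_times.extend(fp - 0.5 + 0.05 + 0.1 * np.arange(5))
        st_ = SpikeTrain("n0", np.sort(spike_times))
        mean, sd = baseline_stats(st_, TrialTable(trials))
        assert mean == pytest.approx(10.0)
        assert sd == pytest.approx(0.0)

    def test_empty_train(self, trials_200):
        mean, sd = baseline_stats(SpikeTrain("n0", np.array([])), trials_200)
        assert (mean, sd) == (0.0, 0.0)

    def test_homogeneous_poisson_closed_form(self, fast_trial_config):
        trials = synth.generate_trials(500, fast_trial_config, rng_seed=0)
        params = synth.NeuronParams.da(
            fp_delta=0, cs_delta_lr=0, cs_delta_sr=0,
            rw_delta_predicted=0, rw_delta_unpredicted=0,
        )
        st_ = synth.generate_spike_train(trials, params, rng_seed=8)
        mean, sd = baseline_stats(st_, trials, bin_width=0.1)
        assert mean == pytest.approx(5.0, abs=0.5)
        # per-bin rate SD for Poisson(rate*bin)/bin = sqrt(rate/bin)
        assert sd == pytest.approx(np.sqrt(5.0 / 0.1), rel=0.10)

    def test_too_few_trials(self):
        with pytest.raises(ValueError, match="too few"):
            baseline_stats(SpikeTrain("n0", np.array([1.0])), _single_trial())


class TestPSTH:
    def test_hand_counted_bins(self):
        trials = _single_trial(cs_onset=10.0)
        st_ = SpikeTrain("n0", np.array([10.005, 10.015]))
        h = psth(st_, trials, align="CS", bin_width=0.01, window=(0.0, 0.05))
        assert list(h.rates) == [100.0, 100.0, 0.0, 0.0, 0.0]
        assert h.counts.sum() == 2

    def test_conservation_identity(self, small_session):
        session, _ = small_session
        nid = sorted(session.spikes)[0]
        h = psth(session.spikes[nid], session.trials, align="CS",
                 bin_width=0.01, window=(-0.5, 1.0))
        total = 0
        for t in session.trials:
            if not t.valid:
                continue
            times = session.spikes[nid].spike_times
            total += int(
                np.searchsorted(times, t.cs_onset + 1.0)
                - np.searchsorted(times, t.cs_onset - 0.5)
            )
        assert int(h.counts.sum()) == total

    def test_invalid_trials_excluded(self, trials_200):
        st_ = SpikeTrain("n0", np.array([t.cs_onset + 0.05 for t in trials_200]))
        h = psth(st_, trials_200, align="CS", window=(0.0, 0.1))
        n_valid = sum(t.valid for t in trials_200)
        assert h.n_trials == n_valid

    def test_empty_selection(self, trials_200):
        with pytest.raises(ValueError, match="empty"):
            psth(SpikeTrain("n", np.array([])), TrialTable(), align="CS")


class TestWindowRate:
    def test_hand_count(self):
        trials = _single_trial(10.0)
        st_ = SpikeTrain("n0", np.array([10.11, 10.15, 10.22, 10.29]))
        rates = window_rate(st_, trials, "CS", (0.1, 0.3))
        assert rates.tolist() == [20.0]

    def test_half_open_boundary(self):
        trials = _single_trial(10.0)
        st_ = SpikeTrain("n0", np.array([10.1, 10.3]))  # end excluded, start included
        rates = window_rate(st_, trials, "CS", (0.1, 0.3))
        assert rates.tolist() == [5.0]

    def test_no_spikes(self):
        rates = window_rate(SpikeTrain("n0", np.array([])), _single_trial(), "CS", (0.1, 0.3))
        assert rates.tolist() == [0.0]

    def test_bad_window(self):
        with pytest.raises(ValueError):
            window_rate(SpikeTrain("n0", np.array([])), _single_trial(), "CS", (0.3, 0.1))


class TestSignTest:
    def test_all_positive_n8(self):
        _k, p = exact_sign_test(np.ones(8), np.zeros(8))
        assert p == pytest.approx(2 * 0.5**8)
        assert p == 0.0078125

    def test_all_ties_report_one(self):
        _k, p = exact_sign_test(np.ones(6), np.ones(6))
        assert p == 1.0

    @given(n=st.integers(1, 12), k=st.integers(0, 12))
    @settings(max_examples=120, deadline=None)
    def test_matches_exhaustive_enumeration(self, n, k):
        k = min(k, n)
        p_impl = sign_test_p(k, n - k)
        # oracle: enumerate all 2^n sign patterns
        ge = sum(1 for pat in itertools.product([0, 1], repeat=n) if sum(pat) >= k)
        le = sum(1 for pat in itertools.product([0, 1], repeat=n) if sum(pat) <= k)
        p_enum = min(2**n, 2 * min(ge, le)) / 2**n
        assert p_impl == p_enum

    def test_one_sided_tails(self):
        assert sign_test_p(8, 0, tail="greater") == 0.5**8
        assert sign_test_p(0, 8, tail="less") == 0.5**8


class TestCompareWindowRates:
    def test_paired_identical_sign_test(self):
        a = np.arange(8.0)
        stat, p = compare_window_rates(a, a, test="sign_test")
        assert p == 1.0

    def test_welch_against_permutation_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.7, 1.2, 10)
        _t, p = compare_window_rates(a, b, test="welch_t")

        def welch_stat(x, y):
            return (x.mean() - y.mean()) / np.sqrt(
                x.var(ddof=1) / x.size + y.var(ddof=1) / y.size
            )

        pooled = np.concatenate([a, b])
        t_obs = abs(welch_stat(a, b))
        hits = 0
        n_perm = 10000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            hits += abs(welch_stat(perm[:10], perm[10:])) >= t_obs
        p_perm = hits / n_perm
        assert abs(p - p_perm) < 0.02

    def test_wilcoxon_all_ties(self):
        a = np.arange(8.0)
        assert compare_window_rates(a, a, test="wilcoxon_signed_rank") == (0.0, 1.0)

    def test_insufficient_n(self):
        with pytest.raises(ValueError, match="insufficient"):
            compare_window_rates(np.ones(3), np.zeros(3), test="wilcoxon_signed_rank")

    def test_one_sample_t(self):
        rng = np.random.default_rng(1)
        x = rng.normal(2.0, 1.0, 30)
        t, p = compare_window_rates(x, 0.0, test="one_sample_t")
        assert t > 5 and p < 1e-6


class TestResponseLatency:
    def test_step_response_at_100ms(self):
        trials = _single_trial(10.0)
        # 500 Hz burst from CS+0.1 to CS+0.3, silence elsewhere
        st_ = SpikeTrain("n0", 10.0 + np.arange(0.1, 0.3, 0.002))
        res = response_latency(st_, trials, baseline=(5.0, 1.0))
        assert res.latency_ms == pytest.approx(100.0, abs=10.0)

    def test_flat_train_undefined(self, fast_trial_config):
        trials = synth.generate_trials(100, fast_trial_config, rng_seed=0)
        params = synth.NeuronParams.da(
            fp_delta=0, cs_delta_lr=0, cs_delta_sr=0,
            rw_delta_predicted=0, rw_delta_unpredicted=0,
        )
        st_ = synth.generate_spike_train(trials, params, rng_seed=1)
        base = baseline_stats(st_, trials)
        res = response_latency(st_, trials, baseline=base, criterion_k=3.0)
        assert res.latency_ms is None

    def test_monotone_in_criterion_k(self, fast_trial_config):
        trials = synth.generate_trials(100, fast_trial_config, rng_seed=2)
        for seed in range(5):
            st_ = synth.generate_spike_train(
                trials, synth.NeuronParams.da(response_latency=120.0), rng_seed=seed
            )
            base = baseline_stats(st_, trials)
            lats = []
            for k in (1.0, 2.0, 3.0):
                res = response_latency(st_, trials, baseline=base,
                                       criterion_k=k, condition="LR")
                lats.append(res.latency_ms)
            defined = [x for x in lats if x is not None]
            assert defined == sorted(defined)
            # once undefined at some k, it stays undefined for larger k
            seen_none = False
            for x in lats:
                if x is None:
                    seen_none = True
                elif seen_none:
                    pytest.fail("latency reappeared at larger k")


class TestDiscriminationOnset:
    def test_sixteen_neurons_divergence_at_120ms(self):
        n_bins = 400  # 1 ms bins over 0-400 ms
        lr = np.zeros((16, n_bins))
        sr = np.zeros((16, n_bins))
        lr[:, 120:] = 1.0
        res = discrimination_onset(lr, sr, bin_width=0.001)
        assert res.onsets_ms[15] == pytest.approx(120.0)
        assert res.onsets_ms[50] == pytest.approx(120.0)
        assert res.p_values[120] == pytest.approx(2 * 0.5**16)

    def test_identical_rates_undefined(self):
        x = np.random.default_rng(0).poisson(5, size=(16, 40)).astype(float)
        res = discrimination_onset(x, x, bin_width=0.01)
        assert res.onsets_ms[15] is None and res.onsets_ms[50] is None

    def test_short_runs_do_not_qualify(self):
        n_bins = 100
        lr = np.zeros((16, n_bins))
        sr = np.zeros((16, n_bins))
        # runs of 10 significant 1-ms bins separated by gaps: span 10 ms <= 15
        for start in (20, 40, 60, 80):
            lr[:, start:start + 10] = 1.0
        res = discrimination_onset(lr, sr, bin_width=0.001)
        assert res.onsets_ms[15] is None

    def test_persistence_ordering(self):
        lr = np.zeros((16, 200))
        sr = np.zeros((16, 200))
        lr[:, 30:50] = 1.0   # 20 ms run at 1 ms bins: qualifies for >15 only
        lr[:, 100:180] = 1.0  # 80 ms run: qualifies for both
        res = discrimination_onset(lr, sr, bin_width=0.001)
        assert res.onsets_ms[15] == pytest.approx(30.0)
        assert res.onsets_ms[50] == pytest.approx(100.0)
        assert res.onsets_ms[50] >= res.onsets_ms[15]

    def test_underpowered(self):
        x = np.zeros((5, 10))
        with pytest.raises(ValueError, match="underpowered.*6"):
            discrimination_onset(x, x)


class TestWaveformStability:
    def test_identical_templates(self):
        wf = synth.generate_waveform(synth.NeuronParams.da(), noise_sd=0.0)
        r, stable = waveform_stability([wf, wf])
        assert r[0, 1] == pytest.approx(1.0)
        assert stable

    def test_negated_template_unstable(self):
        wf = synth.generate_waveform(synth.NeuronParams.da(), noise_sd=0.0)
        neg = WaveformTemplate(-wf.samples, wf.sample_interval_ms)
        r, stable = waveform_stability([wf, neg])
        assert r[0, 1] == pytest.approx(-1.0)
        assert not stable

    def test_noisy_templates_stable_monte_carlo(self):
        # noise SD = 5% of unit peak; >= 99/100 template pairs stable
        params = synth.NeuronParams.da()
        stable_count = 0
        for seed in range(100):
            a = synth.generate_waveform(params, rng_seed=2 * seed, noise_sd=0.05)
            b = synth.generate_waveform(params, rng_seed=2 * seed + 1, noise_sd=0.05)
            _r, stable = waveform_stability([a, b])
            stable_count += stable
        assert stable_count >= 99

    def test_resampling_and_refusal(self):
        a = synth.generate_waveform(synth.NeuronParams.da(), n_samples=64, noise_sd=0.0)
        b = synth.generate_waveform(synth.NeuronParams.da(), n_samples=48, noise_sd=0.0)
        r, _stable = waveform_stability([a, b])
        assert r.shape == (2, 2) and -1.0 <= r[0, 1] <= 1.0
        with pytest.raises(ValueError, match="length"):
            waveform_stability([a, b], resample=False)
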