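"""Parameter-recovery experiments on synthetic sessions.

Each experiment generates data with known ground truth, runs the analysis
path under test, and reports a machine-readable verdict.  The suite
defines its own oracles (closed forms or programmed parameters), never the
analysis path it is checking.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import behavior, psycho, spikes, synth
from .session import TrialTable

__all__ = [
    "latency_recovery",
    "onset_recovery",
    "classification_accuracy",
    "inactivation_recovery",
    "welch_type1_calibration",
    "psychometric_recovery",
    "conservation_check",
    "run_recovery_suite",
]

_FAST_TRIALS = synth.TrialConfig(
    inter_trial_interval=0.3, post_reward_pause=0.5, invalid_trial_prob=0.0
)


def _per_neuron_cs_rates(
    trials: TrialTable, params_list, rng, condition: str,
    bin_width: float, window: tuple[float, float],
    train_cache: dict,
) -> np.ndarray:
    rows = []
    for i, params in enumerate(params_list):
        st = train_cache[i]
        h = spikes.psth(st, trials, align="CS", condition=condition,
                        bin_width=bin_width, window=window)
        rows.append(h.rates)
    return np.asarray(rows)


def latency_recovery(
    n_seeds: int = 100,
    n_neurons: int = 24,
    n_trials_per_condition: int = 60,
    latency_range_ms: tuple[float, float] = (60.0, 160.0),
    bin_width: float = 0.01,
    seed: int = 0,
) -> dict:
    """Recover programmed CS-response latencies with the 2 SD criterion.

    Latencies are drawn uniformly on ``latency_range_ms`` per neuron; each
    neuron is estimated from its LR-trial PSTH against its own pre-FP
    baseline.  Reports the pooled fraction of neurons recovered within one
    bin (10 ms) and the pooled mean estimation error.
    """
    root = np.random.default_rng(seed)
    errors = []
    per_seed_mean_err = []
    for _ in range(n_seeds):
        rng = np.random.default_rng(root.integers(2**63 - 1))
        trials = synth.generate_trials(
            2 * n_trials_per_condition, _FAST_TRIALS, rng_seed=int(rng.integers(2**31 - 1))
        )
        seed_errs = []
        for _n in range(n_neurons):
            lat = float(rng.uniform(*latency_range_ms))
            params = synth.NeuronParams.da(response_latency=lat, fp_delta=0.0)
            st = synth.generate_spike_train(
                trials, params, rng_seed=int(rng.integers(2**31 - 1))
            )
            base = spikes.baseline_stats(st, trials)
            res = spikes.response_latency(
                st, trials, align="CS", baseline=base,
                bin_width=bin_width, criterion_k=2.0, condition="LR",
            )
            if res.latency_ms is None:
                seed_errs.append(np.inf)
            else:
                seed_errs.append(res.latency_ms - lat)
        errors.extend(seed_errs)
        finite = [e for e in seed_errs if np.isfinite(e)]
        per_seed_mean_err.append(np.mean(finite) if finite else np.inf)
    errors = np.asarray(errors)
    tol = bin_width * 1000.0
    return {
        "n_seeds": n_seeds,
        "n_neurons_total": int(errors.size),
        "fraction_within_one_bin": float(np.mean(np.abs(errors) <= tol)),
        "pooled_mean_error_ms": float(np.mean(errors[np.isfinite(errors)])),
        "fraction_seeds_mean_within_10ms": float(
            np.mean(np.abs(np.asarray(per_seed_mean_err)) <= 10.0)
        ),
    }


def onset_recovery(
    n_seeds: int = 100,
    n_neurons: int = 24,
    n_trials_per_condition: int = 60,
    divergence_ms: float = 120.0,
    delta_lr: float = 25.0,
    delta_sr: float = 5.0,
    bin_width: float = 0.01,
    seed: int = 0,
) -> dict:
    """Recover a programmed LR/SR divergence time with the sign-test onset.

    All neurons share latency = ``divergence_ms`` and a rate difference of
    ``delta_lr - delta_sr`` (>= 10 Hz by default).  Reports the fraction of
    replicates with onset_15 in [T, T+25] ms and whether
    onset_50 >= onset_15 held in every replicate where both were defined.
    """
    root = np.random.default_rng(seed)
    onset15, onset50 = [], []
    window = (0.0, 0.4)
    for _ in range(n_seeds):
        rng = np.random.default_rng(root.integers(2**63 - 1))
        trials = synth.generate_trials(
            2 * n_trials_per_condition, _FAST_TRIALS, rng_seed=int(rng.integers(2**31 - 1))
        )
        lr_rows, sr_rows = [], []
        for _n in range(n_neurons):
            params = synth.NeuronParams.da(
                response_latency=divergence_ms, fp_delta=0.0,
                cs_delta_lr=delta_lr, cs_delta_sr=delta_sr,
            )
            st = synth.generate_spike_train(
                trials, params, rng_seed=int(rng.integers(2**31 - 1))
            )
            lr_rows.append(
                spikes.psth(st, trials, "CS", "LR", bin_width, window).rates
            )
            sr_rows.append(
                spikes.psth(st, trials, "CS", "SR", bin_width, window).rates
            )
        res = spikes.discrimination_onset(
            np.asarray(lr_rows), np.asarray(sr_rows),
            bin_width=bin_width, t_start=window[0],
        )
        onset15.append(res.onsets_ms[15])
        onset50.append(res.onsets_ms[50])
    ok15 = [
        o is not None and divergence_ms <= o <= divergence_ms + 25.0 for o in onset15
    ]
    order_ok = all(
        o50 >= o15
        for o15, o50 in zip(onset15, onset50)
        if o15 is not None and o50 is not None
    )
    return {
        "n_seeds": n_seeds,
        "fraction_onset15_within_T_T25": float(np.mean(ok15)),
        "onset50_ge_onset15_always": bool(order_ok),
        "onset15_defined": int(sum(o is not None for o in onset15)),
        "onset50_defined": int(sum(o is not None for o in onset50)),
    }


def classification_accuracy(
    n_da: int = 50,
    n_snr: int = 50,
    n_trials: int = 60,
    waveform_noise_sd: float = 0.02,
    seed: int = 0,
) -> dict:
    """Label a well-separated two-cluster synthetic population.

    Baseline rates and widths are estimated from generated trains and
    templates (not read from the ground truth) and then classified.
    """
    rng = np.random.default_rng(seed)
    trials = synth.generate_trials(n_trials, _FAST_TRIALS, rng_seed=int(rng.integers(2**31 - 1)))
    correct = 0
    total = 0
    for kind, count in (("DA", n_da), ("SNr", n_snr)):
        for _i in range(count):
            if kind == "DA":
                params = synth.NeuronParams.da(
                    baseline_rate=float(rng.uniform(2.0, 8.0)),
                    waveform_width=float(rng.uniform(0.5, 0.8)),
                )
            else:
                params = synth.NeuronParams.snr(
                    baseline_rate=float(rng.uniform(50.0, 70.0)),
                    waveform_width=float(rng.uniform(0.15, 0.35)),
                )
            st = synth.generate_spike_train(trials, params, rng_seed=int(rng.integers(2**31 - 1)))
            wf = synth.generate_waveform(
                params, rng_seed=int(rng.integers(2**31 - 1)), noise_sd=waveform_noise_sd
            )
            mean, _sd = spikes.baseline_stats(st, trials)
            width = spikes.spike_width(wf)
            label = spikes.classify_neuron(mean, width).label
            correct += int(label == kind)
            total += 1
    return {"n_neurons": total, "accuracy": correct / total}


def inactivation_recovery(
    n_seeds: int = 100,
    n_pairs: int = 13,
    n_pre_trials: int = 60,
    n_during_trials: int = 100,
    seed: int = 0,
) -> dict:
    """Qualitative recovery of the inactivation result on licking.

    Per seed: ``n_pairs`` before/during session pairs generated under the
    anticipation-abolishing mode; success requires Wilcoxon (before vs
    during LR - SR) p < 0.05 and one-sample t (during vs 0) p > 0.05.
    """
    root = np.random.default_rng(seed)
    cfg = dataclasses.replace(_FAST_TRIALS, pre_inactivation_trials=n_pre_trials)
    mode = synth.InactivationMode.abolish()
    both_ok = []
    for _ in range(n_seeds):
        rng = np.random.default_rng(root.integers(2**63 - 1))
        before, during = [], []
        for p in range(n_pairs):
            trials = synth.generate_trials(
                n_pre_trials + n_during_trials, cfg,
                rng_seed=int(rng.integers(2**31 - 1)), inactivation=True,
            )
            licks = synth.generate_licks(
                trials, mode=mode, rng_seed=int(rng.integers(2**31 - 1))
            )
            before.append(
                behavior.cr_summary(licks, trials, epoch="pre_inactivation",
                                    session_id=f"pair{p}")
            )
            during.append(
                behavior.cr_summary(licks, trials, epoch="during_inactivation",
                                    session_id=f"pair{p}")
            )
        report = behavior.inactivation_effect(before, during)
        w_p = report["wilcoxon_before_vs_during"]["p"]
        t_p = report["one_sample_t_during_vs_zero"]["p"]
        both_ok.append(w_p < 0.05 and (np.isnan(t_p) or t_p > 0.05))
    return {"n_seeds": n_seeds, "fraction_success": float(np.mean(both_ok))}


def welch_type1_calibration(
    n_sims: int = 1000, n_per_group: int = 15, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Empirical type-I error of the Welch test on equal-mean fields."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        a = rng.normal(0.0, 1.0, n_per_group)
        b = rng.normal(0.0, 1.0, n_per_group)
        _t, p = behavior.test_affected_vs_intact(a, b)
        rejections += int(p < alpha)
    return {"n_sims": n_sims, "rejection_rate": rejections / n_sims}


def psychometric_recovery(
    n_seeds: int = 100,
    threshold: float = 0.3,
    slope: float = 3.5,
    n_per_contrast: int = 100,
    n_contrasts: int = 7,
    seed: int = 0,
) -> dict:
    """Recover a programmed contrast threshold through the full scoring +
    fitting path (trials are scored geometrically, not read off the
    generator)."""
    root = np.random.default_rng(seed)
    loc = (10.0, 45.0)
    params = synth.PsychoParams(thresholds={loc: threshold}, slope=slope)
    contrasts = list(np.logspace(np.log10(0.02), np.log10(0.9), n_contrasts))
    rel_errors = []
    for _ in range(n_seeds):
        rec = synth.generate_psychometric_trials(
            params, n_per_contrast, contrasts, rng_seed=int(root.integers(2**31 - 1))
        )
        dmap = psycho.build_deficit_map(rec, [loc], neighbor_angle_deg=90.0)
        fit = dmap.fits[loc]
        rel_errors.append(abs(fit.threshold_michelson - threshold) / threshold)
    rel_errors = np.asarray(rel_errors)
    return {
        "n_seeds": n_seeds,
        "fraction_within_10pct": float(np.mean(rel_errors <= 0.10)),
        "median_rel_error": float(np.median(rel_errors)),
    }


def conservation_check(seed: int = 0, n_trials: int = 100) -> dict:
    """Exact mass-balance identities on a generated session.

    PSTH: sum(counts) equals the number of spikes falling in the aligned
    windows; rates * bin_width * n_trials reproduces the counts.  Same for
    the lick-rate profile.
    """
    cfg = synth.SessionConfig(n_trials=n_trials, n_da=1, n_snr=0)
    session, _truth = synth.generate_session(cfg, rng_seed=seed)
    nid = next(iter(session.spikes))
    st = session.spikes[nid]
    window = (-0.5, 1.0)
    h = spikes.psth(st, session.trials, align="CS", bin_width=0.01, window=window)
    manual = 0
    for t in session.trials:
        if not t.valid:
            continue
        lo = np.searchsorted(st.spike_times, t.cs_onset + window[0], side="left")
        hi = np.searchsorted(st.spike_times, t.cs_onset + window[1], side="left")
        manual += int(hi - lo)
    psth_exact = int(h.counts.sum()) == manual
    psth_rates_ok = bool(
        np.allclose(h.rates * h.bin_width * h.n_trials, h.counts, atol=1e-9)
    )

    lwin = (-1.0, 3.5)
    prof = behavior.lick_rate_profile(session.licks, session.trials, window=lwin)
    lt = session.licks.lick_times
    manual_l = 0
    for t in session.trials:
        if not t.valid:
            continue
        lo = np.searchsorted(lt, t.cs_onset + lwin[0], side="left")
        hi = np.searchsorted(lt, t.cs_onset + lwin[1], side="left")
        manual_l += int(hi - lo)
    lick_exact = int(prof.counts.sum()) == manual_l
    lick_rates_ok = bool(
        np.allclose(prof.rates * prof.bin_width * prof.n_trials, prof.counts, atol=1e-9)
    )
    return {
        "psth_counts_exact": psth_exact,
        "psth_rates_consistent": psth_rates_ok,
        "lick_counts_exact": lick_exact,
        "lick_rates_consistent": lick_rates_ok,
    }


# ---------------------------------------------------------------------------

def run_recovery_suite(seed: int = 0, n_seeds: int = 20, full: bool = False) -> pd.DataFrame:
    """Run every recovery experiment and return a verdict table.

    ``full=True`` uses the documented 100-seed/1000-sim sizes; the default
    is a faster smoke configuration.  Failures are verdicts, not errors.
    """
    ns = 100 if full else n_seeds
    nsim = 1000 if full else max(200, 10 * n_seeds)
    rows = []

    r = latency_recovery(n_seeds=ns, seed=seed)
    rows.append(("latency_recovery", "fraction_within_one_bin",
                 r["fraction_within_one_bin"], ">=0.9",
                 r["fraction_within_one_bin"] >= 0.9))
    rows.append(("latency_recovery", "pooled_mean_error_ms",
                 r["pooled_mean_error_ms"], "abs<=10",
                 abs(r["pooled_mean_error_ms"]) <= 10.0))

    r = onset_recovery(n_seeds=ns, seed=seed)
    rows.append(("onset_recovery", "fraction_onset15_within_T_T25",
                 r["fraction_onset15_within_T_T25"], ">=0.9",
                 r["fraction_onset15_within_T_T25"] >= 0.9))
    rows.append(("onset_recovery", "onset50_ge_onset15_always",
                 float(r["onset50_ge_onset15_always"]), "==1",
                 r["onset50_ge_onset15_always"]))

    r = classification_accuracy(seed=seed)
    rows.append(("classification", "accuracy", r["accuracy"], "==1.0",
                 r["accuracy"] == 1.0))

    r = inactivation_recovery(n_seeds=ns, seed=seed)
    rows.append(("inactivation_recovery", "fraction_success",
                 r["fraction_success"], ">=0.9", r["fraction_success"] >= 0.9))

    r = welch_type1_calibration(n_sims=nsim, seed=seed)
    rows.append(("welch_type1", "rejection_rate", r["rejection_rate"],
                 "0.05+-0.02", abs(r["rejection_rate"] - 0.05) <= 0.02))

    r = psychometric_recovery(n_seeds=ns, seed=seed)
    rows.append(("psychometric_recovery", "fraction_within_10pct",
                 r["fraction_within_10pct"], ">=0.9",
                 r["fraction_within_10pct"] >= 0.9))

    r = conservation_check(seed=seed)
    ok = all(r.values())
    rows.append(("conservation", "all_identities_exact", float(ok), "==1", ok))

    return pd.DataFrame(
        rows, columns=["experiment", "metric", "value", "criterion", "passed"]
    )
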