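"""Synthetic session generators with known ground truth.

Spike trains are inhomogeneous Poisson processes generated by thinning,
with event-locked *rectangular* rate bumps (onset = event + latency,
length = response duration).  Rectangular bumps are used because window
means and latencies then have closed forms, which makes recovery tests
exact.  Every generator is bit-reproducible given (seed, params).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .session import (
    CS_DURATIONS,
    LR_REWARD_DELAY,
    SR_REWARD_DELAY,
    LickRecord,
    PsychometricRecord,
    PsychometricTrial,
    Session,
    SessionMetadata,
    SpikeTrain,
    Trial,
    TrialTable,
    WaveformTemplate,
)

__all__ = [
    "TrialConfig",
    "NeuronParams",
    "BehaviorParams",
    "InactivationMode",
    "PsychoParams",
    "SessionConfig",
    "generate_trials",
    "generate_spike_train",
    "generate_licks",
    "generate_waveform",
    "generate_psychometric_trials",
    "generate_session",
    "generate_reversal_dataset",
    "default_grid",
    "polar_to_cartesian",
]

_ROUND = 6  # decimal places kept on every generated event time


def _r6(x: float) -> float:
    return round(float(x), _ROUND)


def polar_to_cartesian(ecc: float, direction_deg: float) -> tuple[float, float]:
    th = np.deg2rad(direction_deg)
    return (ecc * float(np.cos(th)), ecc * float(np.sin(th)))


# ---------------------------------------------------------------------------
# parameter records

@dataclass(frozen=True)
class TrialConfig:
    """Timing and layout of a Pavlovian session.

    Defaults: fixation period uniform on [0.7, 1.2] s before CS onset,
    CS shown for 1.7 s (1.0 s is the other admissible duration), large
    reward 0.17 ml at CS onset + 1.3 s, small reward 0.06 ml at CS offset
    + 1.5 s, CSs pseudo-randomly alternated (balanced within blocks of 2).
    """

    cs_durations: tuple[float, ...] = (1.7,)
    fixation_range: tuple[float, float] = (0.7, 1.2)
    inter_trial_interval: float = 1.0
    post_reward_pause: float = 1.5
    lr_volume: float = 0.17
    sr_volume: float = 0.06
    lr_position: tuple[float, float] = (10.0, 45.0)
    sr_position: tuple[float, float] = (10.0, -45.0)
    invalid_trial_prob: float = 0.05
    field: str = "affected"
    pre_inactivation_trials: int = 60

    def __post_init__(self):
        for d in self.cs_durations:
            if not any(abs(d - a) < 1e-9 for a in CS_DURATIONS):
                raise ValueError(f"CS duration {d} not in {CS_DURATIONS}")
        if not 0 <= self.invalid_trial_prob < 1:
            raise ValueError("invalid_trial_prob must be in [0, 1)")


@dataclass(frozen=True)
class NeuronParams:
    """Rate model of one unit: baseline plus event-locked rectangular bumps.

    Bump amplitudes are generator defaults chosen to emulate the target
    regime (low-rate broad-spike units vs high-rate narrow-spike units);
    baseline/width defaults: DA-like 5 Hz / 0.6 ms, SNr-like 60 Hz / 0.25 ms.
    """

    kind: str = "DA"  # "DA" | "SNr"
    baseline_rate: float = 5.0  # Hz
    fp_delta: float = 20.0  # Hz, both conditions
    cs_delta_lr: float = 25.0
    cs_delta_sr: float = 8.0
    rw_delta_predicted: float = 3.0
    rw_delta_unpredicted: float = 25.0
    response_latency: float = 100.0  # ms
    response_duration: float = 200.0  # ms
    waveform_width: float = 0.6  # ms, trough-to-peak

    def __post_init__(self):
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        for name in (
            "fp_delta", "cs_delta_lr", "cs_delta_sr",
            "rw_delta_predicted", "rw_delta_unpredicted",
        ):
            if getattr(self, name) < -self.baseline_rate:
                raise ValueError(f"{name} may not drive the rate below zero")

    @classmethod
    def da(cls, **overrides) -> "NeuronParams":
        return cls(kind="DA", **overrides)

    @classmethod
    def snr(cls, **overrides) -> "NeuronParams":
        base = dict(
            kind="SNr",
            baseline_rate=60.0,
            fp_delta=10.0,
            cs_delta_lr=10.0,
            cs_delta_sr=10.0,
            rw_delta_predicted=5.0,
            rw_delta_unpredicted=5.0,
            waveform_width=0.25,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class BehaviorParams:
    """Piecewise-constant lick-rate model (absolute rates, events/s)."""

    lick_baseline: float = 0.5
    lick_anticipatory_lr: float = 4.0
    lick_anticipatory_sr: float = 1.5
    lick_post_reward: float = 6.0
    anticipation_onset: float = 0.3  # s after CS onset
    refractory: float = 0.08  # s, enforced by thinning

    def __post_init__(self):
        for name in ("lick_baseline", "lick_anticipatory_lr",
                     "lick_anticipatory_sr", "lick_post_reward"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class InactivationMode:
    """How a muscimol-style inactivation reshapes generated responses.

    ``abolish_anticipation`` sets both anticipatory lick rates to baseline;
    ``nonselective_anticipation`` sets both to the LR anticipatory rate.
    ``cs_response_scale`` multiplies the CS-locked spike-rate bumps and
    ``rw_unmasking`` switches reward bumps to the unpredicted amplitude, on
    during-inactivation trials.
    """

    mode: str = "none"  # none | abolish_anticipation | nonselective_anticipation
    cs_response_scale: float = 1.0
    rw_unmasking: bool = False

    def __post_init__(self):
        if self.mode not in ("none", "abolish_anticipation", "nonselective_anticipation"):
            raise ValueError(f"unknown inactivation mode {self.mode!r}")
        if self.mode == "none" and (self.cs_response_scale != 1.0 or self.rw_unmasking):
            raise ValueError("mode='none' requires cs_response_scale=1 and rw_unmasking=False")
        if not 0.0 <= self.cs_response_scale <= 1.0:
            raise ValueError("cs_response_scale must be in [0, 1]")

    @classmethod
    def abolish(cls) -> "InactivationMode":
        return cls(mode="abolish_anticipation", cs_response_scale=0.0, rw_unmasking=True)

    @classmethod
    def nonselective(cls) -> "InactivationMode":
        return cls(mode="nonselective_anticipation", cs_response_scale=0.0, rw_unmasking=True)


def default_grid(n_directions: int = 3, eccentricities: tuple[float, ...] = (5.0, 10.0, 15.0),
                 hemifield: str = "left") -> list[tuple[float, float]]:
    """Polar grid of target positions in one hemifield.

    Directions are evenly spaced within the hemifield; e.g. 3 directions
    -> {-45, 0, +45} degrees around the horizontal meridian (mirrored for
    the left hemifield).
    """
    if n_directions < 1:
        raise ValueError("need at least one direction")
    dirs = np.linspace(-90.0, 90.0, n_directions + 2)[1:-1]
    if hemifield == "left":
        dirs = ((180.0 - dirs + 180.0) % 360.0) - 180.0
    return [(float(e), float(d)) for e in eccentricities for d in np.atleast_1d(dirs)]


@dataclass(frozen=True)
class PsychoParams:
    """Ground-truth psychometric model per visual-field location.

    Probability correct at contrast c:
        guess + (1 - guess) * Phi(slope*(log c - log threshold) + z_crit)
    where z_crit places the curve exactly at the criterion probability
    (the d'=2 point, 0.8413 under the default equal-variance mapping)
    when c equals the location's threshold.
    """

    thresholds: dict  # (ecc, dir) -> Michelson threshold in (0,1)
    slope: float = 3.5
    guess_rate: float = 0.0
    criterion_p: float = float(norm.cdf(1.0))  # p(correct) at d' = 2

    def __post_init__(self):
        if not self.thresholds:
            raise ValueError("empty grid")
        for loc, thr in self.thresholds.items():
            if not 0 < thr < 1:
                raise ValueError(f"threshold at {loc} outside (0,1)")
        if not 0 <= self.guess_rate < 1:
            raise ValueError("guess_rate must be in [0,1)")
        if not self.guess_rate < self.criterion_p < 1:
            raise ValueError("criterion_p must lie strictly between guess_rate and 1")

    def p_correct(self, loc: tuple[float, float], contrast: float) -> float:
        z_crit = norm.ppf((self.criterion_p - self.guess_rate) / (1 - self.guess_rate))
        z = self.slope * (np.log(contrast) - np.log(self.thresholds[loc])) + z_crit
        return float(self.guess_rate + (1 - self.guess_rate) * norm.cdf(z))


# ---------------------------------------------------------------------------
# trial generator

def generate_trials(
    n_trials: int,
    config: TrialConfig = TrialConfig(),
    rng_seed: int = 0,
    inactivation: bool = False,
) -> TrialTable:
    """Pseudo-randomly interleaved LR/SR trials (balanced within blocks of 2).

    Deterministic for a fixed seed.  With ``inactivation=True`` the first
    ``config.pre_inactivation_trials`` trials are labelled
    ``pre_inactivation`` and the remainder ``during_inactivation``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(rng_seed)

    conditions: list[str] = []
    while len(conditions) < n_trials:
        block = ["LR", "SR"]
        rng.shuffle(block)
        conditions.extend(block)
    conditions = conditions[:n_trials]

    trials = []
    t = config.inter_trial_interval
    for i, cond in enumerate(conditions):
        fp_onset = t
        fix = rng.uniform(*config.fixation_range)
        cs_onset = fp_onset + fix
        dur = float(rng.choice(config.cs_durations))
        cs_offset = cs_onset + dur
        if cond == "LR":
            reward_time = cs_onset + LR_REWARD_DELAY
            volume = config.lr_volume
            position = config.lr_position
        else:
            reward_time = cs_offset + SR_REWARD_DELAY
            volume = config.sr_volume
            position = config.sr_position
        valid = bool(rng.random() >= config.invalid_trial_prob)
        if inactivation:
            epoch = "pre_inactivation" if i < config.pre_inactivation_trials else "during_inactivation"
        else:
            epoch = "none"
        trials.append(
            Trial(
                trial_id=i,
                condition=cond,
                field=config.field,
                epoch=epoch,
                fp_onset=_r6(fp_onset),
                cs_onset=_r6(cs_onset),
                cs_offset=_r6(cs_offset),
                reward_time=_r6(reward_time),
                reward_volume=volume,
                cs_position=position,
                valid=valid,
            )
        )
        t = max(cs_offset, reward_time) + config.post_reward_pause + config.inter_trial_interval
    return TrialTable(trials)


def session_duration(trials: TrialTable, pad: float = 2.0) -> float:
    last = 0.0
    for t in trials:
        last = max(last, t.cs_offset, t.reward_time or 0.0)
    return _r6(last + pad)


# ---------------------------------------------------------------------------
# point-process machinery

def _thinned_poisson(
    rng: np.random.Generator,
    t_end: float,
    baseline: float,
    starts: np.ndarray,
    ends: np.ndarray,
    deltas: np.ndarray,
) -> np.ndarray:
    """Inhomogeneous Poisson times on [0, t_end) by thinning.

    Rate(t) = max(0, baseline + sum of rectangular bumps covering t); the
    dominating rate is the exact maximum of that step function.
    """
    if deltas.size:
        edges = np.concatenate([starts, ends])
        steps = np.concatenate([deltas, -deltas])
        order = np.argsort(edges, kind="stable")
        edges = edges[order]
        cum = np.cumsum(steps[order])
        lam_max = baseline + max(0.0, float(cum.max()))
    else:
        edges = cum = None
        lam_max = baseline
    lam_max = max(lam_max, 1e-12)
    n = rng.poisson(lam_max * t_end)
    cand = np.sort(rng.uniform(0.0, t_end, size=n))
    if cand.size == 0 or edges is None:
        return cand
    idx = np.searchsorted(edges, cand, side="right") - 1
    rate = baseline + np.where(idx >= 0, cum[np.clip(idx, 0, None)], 0.0)
    rate = np.clip(rate, 0.0, None)
    keep = rng.uniform(0.0, lam_max, size=cand.size) < rate
    return cand[keep]


def _strictly_increasing(times: np.ndarray) -> np.ndarray:
    """Round to the serialization grid and break ties by +1 us."""
    times = np.round(np.sort(times), _ROUND)
    if times.size < 2:
        return times
    eps = 10.0 ** (-_ROUND)
    shift = np.arange(times.size) * eps
    times = np.maximum.accumulate(times - shift) + shift
    return np.round(times, _ROUND)


def _mode_applies(trial: Trial, trials: TrialTable, mode: InactivationMode) -> bool:
    """Inactivation effects apply to during-inactivation trials; if the
    table has no epoch labels at all, they apply to every trial."""
    if mode.mode == "none":
        return False
    has_epochs = any(t.epoch == "during_inactivation" for t in trials)
    return trial.epoch == "during_inactivation" if has_epochs else True


def generate_spike_train(
    trials: TrialTable,
    params: NeuronParams,
    rng_seed: int = 0,
    neuron_id: str = "n0",
    mode: InactivationMode = InactivationMode(),
    t_end: float | None = None,
) -> SpikeTrain:
    """Spike train with baseline rate plus event-locked rectangular bumps.

    Reward bumps use ``rw_delta_predicted`` on trials where a CS response
    precedes the reward and ``rw_delta_unpredicted`` when the CS signal is
    suppressed (``mode.rw_unmasking`` on during-inactivation trials).
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    rng = np.random.default_rng(rng_seed)
    lat = params.response_latency / 1000.0
    dur = params.response_duration / 1000.0

    starts, ends, deltas = [], [], []
    for t in trials:
        suppressed = _mode_applies(t, trials, mode)
        bumps = [(t.fp_onset, params.fp_delta)]
        cs_delta = params.cs_delta_lr if t.condition == "LR" else params.cs_delta_sr
        if suppressed:
            cs_delta *= mode.cs_response_scale
        bumps.append((t.cs_onset, cs_delta))
        if t.reward_time is not None:
            rw_delta = (
                params.rw_delta_unpredicted
                if (suppressed and mode.rw_unmasking)
                else params.rw_delta_predicted
            )
            bumps.append((t.reward_time, rw_delta))
        for onset, delta in bumps:
            if delta != 0.0:
                starts.append(onset + lat)
                ends.append(onset + lat + dur)
                deltas.append(delta)

    T = t_end if t_end is not None else session_duration(trials)
    times = _thinned_poisson(
        rng, T, params.baseline_rate,
        np.asarray(starts, dtype=float),
        np.asarray(ends, dtype=float),
        np.asarray(deltas, dtype=float),
    )
    return SpikeTrain(neuron_id=neuron_id, spike_times=_strictly_increasing(times))


def generate_licks(
    trials: TrialTable,
    params: BehaviorParams = BehaviorParams(),
    mode: InactivationMode = InactivationMode(),
    rng_seed: int = 0,
    t_end: float | None = None,
    position_rates: dict[str, float] | None = None,
) -> LickRecord:
    """Poisson lick process with absolute piecewise-constant rates.

    Baseline everywhere; an anticipatory rate from ``anticipation_onset``
    after CS onset until reward delivery (condition-specific unless
    ``position_rates`` maps 'upper'/'lower' CS positions to rates, as in
    reversal learning); a post-reward burst for 1 s after reward.  An
    80 ms refractory period is enforced by thinning.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    rng = np.random.default_rng(rng_seed)
    base = params.lick_baseline

    starts, ends, deltas = [], [], []
    for t in trials:
        inactivated = _mode_applies(t, trials, mode)
        if position_rates is not None:
            key = "upper" if t.cs_position[1] >= 0 else "lower"
            antic = position_rates[key]
        else:
            antic = (
                params.lick_anticipatory_lr
                if t.condition == "LR"
                else params.lick_anticipatory_sr
            )
        if inactivated:
            if mode.mode == "abolish_anticipation":
                antic = base
            elif mode.mode == "nonselective_anticipation":
                antic = params.lick_anticipatory_lr
        a0 = t.cs_onset + params.anticipation_onset
        a1 = t.reward_time if t.reward_time is not None else t.cs_offset
        if a1 > a0 and antic != base:
            starts.append(a0)
            ends.append(a1)
            deltas.append(antic - base)
        if t.reward_time is not None and params.lick_post_reward != base:
            starts.append(t.reward_time)
            ends.append(t.reward_time + 1.0)
            deltas.append(params.lick_post_reward - base)

    T = t_end if t_end is not None else session_duration(trials)
    times = _thinned_poisson(
        rng, T, base,
        np.asarray(starts, dtype=float),
        np.asarray(ends, dtype=float),
        np.asarray(deltas, dtype=float),
    )
    # refractory thinning: drop events closer than `refractory` to the last kept one
    kept = []
    last = -np.inf
    for x in times:
        if x - last >= params.refractory:
            kept.append(x)
            last = x
    return LickRecord(_strictly_increasing(np.asarray(kept)))


# ---------------------------------------------------------------------------
# waveform generator

def generate_waveform(
    params: NeuronParams,
    rng_seed: int = 0,
    n_samples: int = 64,
    sample_interval_ms: float = 0.025,
    noise_sd: float = 0.0,
    epoch_label: str = "avg",
    trough_index: int = 16,
) -> WaveformTemplate:
    """Biphasic template whose trough-to-peak time equals the programmed
    width to within half a sample.

    Built as a negative Gaussian trough followed by a positive Gaussian
    peak separated by ``params.waveform_width``; Gaussian SDs are width/4
    so the extrema shift by < 1e-3 ms.
    """
    w = params.waveform_width
    dt = sample_interval_ms
    if w <= 2 * dt:
        raise ValueError(f"width {w} ms not representable at {dt} ms sampling")
    t0 = trough_index * dt
    t1 = t0 + w
    if t1 >= (n_samples - 2) * dt:
        raise ValueError("width not representable: peak falls outside the template")
    rng = np.random.default_rng(rng_seed)
    t = np.arange(n_samples) * dt
    sigma = w / 4.0
    samples = -np.exp(-0.5 * ((t - t0) / sigma) ** 2) + 0.7 * np.exp(
        -0.5 * ((t - t1) / sigma) ** 2
    )
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, size=n_samples)
    return WaveformTemplate(
        samples=np.round(samples, _ROUND),
        sample_interval_ms=dt,
        epoch_label=epoch_label,
    )


# ---------------------------------------------------------------------------
# psychometric generator

def generate_psychometric_trials(
    params: PsychoParams,
    n_per_cell: int,
    contrasts: list[float],
    rng_seed: int = 0,
) -> PsychometricRecord:
    """``n_per_cell`` saccade trials per location x contrast.

    Correct trials land exactly on the target; incorrect trials are placed
    at the antipodal point (distance 2 x eccentricity from the target),
    outside any plausible scoring window.
    """
    if not params.thresholds:
        raise ValueError("empty grid")
    for c in contrasts:
        if not 0 < c < 1:
            raise ValueError(f"contrast {c} outside (0,1)")
    rng = np.random.default_rng(rng_seed)
    trials = []
    for loc in sorted(params.thresholds):
        for c in contrasts:
            p = params.p_correct(loc, c)
            correct = rng.random(n_per_cell) < p
            tx, ty = polar_to_cartesian(*loc)
            for ok in correct:
                endpoint = (tx, ty) if ok else (-tx, -ty)
                trials.append(
                    PsychometricTrial(
                        target_position=loc,
                        michelson_contrast=float(c),
                        saccade_endpoint=(round(endpoint[0], _ROUND), round(endpoint[1], _ROUND)),
                        responded_within_1s=True,
                    )
                )
    return PsychometricRecord(trials)


# ---------------------------------------------------------------------------
# whole-session assembly

@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to synthesize one session (plus its ground truth)."""

    n_trials: int = 200
    n_da: int = 2
    n_snr: int = 1
    trial_config: TrialConfig = TrialConfig()
    behavior: BehaviorParams = BehaviorParams()
    mode: InactivationMode = InactivationMode()
    inactivation: bool = False
    latency_range_ms: tuple[float, float] = (60.0, 160.0)
    waveform_noise_sd: float = 0.02
    include_psychometrics: bool = False
    psycho_n_per_cell: int = 20
    psycho_contrasts: tuple[float, ...] = (0.02, 0.05, 0.1, 0.2, 0.4, 0.65, 0.9)
    subject: str = "synthetic"
    date: str = "1970-01-01"

    def __post_init__(self):
        if self.inactivation and self.mode.mode == "none":
            raise ValueError("inactivation sessions need a non-none mode")


def _lesioned_psycho_params(field: str) -> PsychoParams:
    grid = default_grid(3, (5.0, 10.0, 15.0), hemifield="right")
    affected_factor = 3.0 if field == "affected" else 1.0
    thresholds = {loc: min(0.9, 0.1 * affected_factor) for loc in grid}
    return PsychoParams(thresholds=thresholds)


def generate_session(
    config: SessionConfig = SessionConfig(), rng_seed: int = 0
) -> tuple[Session, dict]:
    """Build a full synthetic session and the ground-truth record that a
    recovery test needs (per-neuron parameters including latency, behavior
    parameters, inactivation mode)."""
    rng = np.random.default_rng(rng_seed)
    seeds = rng.integers(0, 2**31 - 1, size=4 + 2 * (config.n_da + config.n_snr))
    trials = generate_trials(
        config.n_trials, config.trial_config, rng_seed=int(seeds[0]),
        inactivation=config.inactivation,
    )
    t_end = session_duration(trials)
    licks = generate_licks(
        trials, config.behavior, mode=config.mode, rng_seed=int(seeds[1]), t_end=t_end
    )

    spikes: dict[str, SpikeTrain] = {}
    waveforms: dict[str, list[WaveformTemplate]] = {}
    truth_neurons = {}
    k = 4
    for i in range(config.n_da):
        lat = float(rng.uniform(*config.latency_range_ms))
        params = NeuronParams.da(response_latency=lat)
        nid = f"da{i:02d}"
        spikes[nid] = generate_spike_train(
            trials, params, rng_seed=int(seeds[k]), neuron_id=nid,
            mode=config.mode, t_end=t_end,
        )
        waveforms[nid] = [
            generate_waveform(params, rng_seed=int(seeds[k + 1]),
                              noise_sd=config.waveform_noise_sd)
        ]
        truth_neurons[nid] = dataclasses.asdict(params)
        k += 2
    for i in range(config.n_snr):
        params = NeuronParams.snr(response_latency=float(rng.uniform(60.0, 120.0)))
        nid = f"snr{i:02d}"
        spikes[nid] = generate_spike_train(
            trials, params, rng_seed=int(seeds[k]), neuron_id=nid,
            mode=config.mode, t_end=t_end,
        )
        waveforms[nid] = [
            generate_waveform(params, rng_seed=int(seeds[k + 1]),
                              noise_sd=config.waveform_noise_sd)
        ]
        truth_neurons[nid] = dataclasses.asdict(params)
        k += 2

    psychometrics = None
    psycho_truth = None
    if config.include_psychometrics:
        pparams = _lesioned_psycho_params(config.trial_config.field)
        psychometrics = generate_psychometric_trials(
            pparams, config.psycho_n_per_cell, list(config.psycho_contrasts),
            rng_seed=int(seeds[2]),
        )
        psycho_truth = {
            "thresholds": {f"{e}_{d}": thr for (e, d), thr in pparams.thresholds.items()},
            "slope": pparams.slope,
            "guess_rate": pparams.guess_rate,
            "criterion_p": pparams.criterion_p,
        }

    metadata = SessionMetadata(
        subject=config.subject,
        date=config.date,
        field=config.trial_config.field,
        inactivation=config.inactivation,
        extra={"duration_s": t_end, "rng_seed": rng_seed},
    )
    session = Session(
        trials=trials, spikes=spikes, waveforms=waveforms, licks=licks,
        psychometrics=psychometrics, metadata=metadata,
    )
    truth = {
        "rng_seed": rng_seed,
        "n_trials": config.n_trials,
        "neurons": truth_neurons,
        "behavior": dataclasses.asdict(config.behavior),
        "mode": dataclasses.asdict(config.mode),
        "psychometrics": psycho_truth,
    }
    return session, truth


# ---------------------------------------------------------------------------
# reversal learning

def generate_reversal_dataset(
    n_days: int,
    switch_days: list[int],
    learning_rate: float,
    rng_seed: int = 0,
    n_trials: int = 200,
    trial_config: TrialConfig = TrialConfig(),
    behavior: BehaviorParams = BehaviorParams(),
) -> tuple[list[Session], dict]:
    """Daily sessions whose per-position anticipatory lick rates relax
    exponentially (per-day fraction ``learning_rate``) toward the current
    CS-position -> reward assignment after each switch.

    Day 1 starts fully adapted to upper=LR.  ``switch_days`` flip the
    assignment at the start of the named day (1-based).
    """
    if any(not 1 <= d <= n_days for d in switch_days):
        raise ValueError("switch_days must lie within [1, n_days]")
    if not 0.0 <= learning_rate <= 1.0:
        raise ValueError("learning_rate must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    sessions = []
    w = 1.0       # degree to which the upper position behaves as LR
    target = 1.0  # current true assignment (1: upper=LR)
    truth_days = []
    for day in range(1, n_days + 1):
        if day in switch_days:
            target = 1.0 - target
        w = w + learning_rate * (target - w)
        upper_is_lr = target >= 0.5
        cfg = dataclasses.replace(
            trial_config,
            lr_position=(10.0, 45.0) if upper_is_lr else (10.0, -45.0),
            sr_position=(10.0, -45.0) if upper_is_lr else (10.0, 45.0),
        )
        trials = generate_trials(n_trials, cfg, rng_seed=int(rng.integers(2**31 - 1)))
        rate_upper = w * behavior.lick_anticipatory_lr + (1 - w) * behavior.lick_anticipatory_sr
        rate_lower = (1 - w) * behavior.lick_anticipatory_lr + w * behavior.lick_anticipatory_sr
        licks = generate_licks(
            trials, behavior, rng_seed=int(rng.integers(2**31 - 1)),
            position_rates={"upper": rate_upper, "lower": rate_lower},
        )
        metadata = SessionMetadata(
            subject="synthetic",
            date=f"day{day:03d}",
            field=trial_config.field,
            inactivation=False,
            extra={
                "day": day,
                "assignment_upper": "LR" if upper_is_lr else "SR",
                "duration_s": session_duration(trials),
            },
        )
        sessions.append(
            Session(trials=trials, spikes={}, waveforms={}, licks=licks, metadata=metadata)
        )
        truth_days.append({"day": day, "w_upper_lr": w, "assignment_upper": "LR" if upper_is_lr else "SR"})
    truth = {
        "learning_rate": learning_rate,
        "switch_days": list(switch_days),
        "behavior": dataclasses.asdict(behavior),
        "days": truth_days,
    }
    return sessions, truth
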