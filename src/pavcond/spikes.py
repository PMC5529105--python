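"""Neuron classification, PSTHs, window firing-rate statistics, response
latency, discrimination onset, and waveform stability.

Conventions
-----------
* All event windows are half-open: ``[event + start, event + end)``.
* Invalid trials are excluded from every statistic.
* The baseline epoch defaults to the 0.5 s before fixation-point onset,
  the only task-event-free epoch.
* The latency criterion is the first bin whose across-trial mean rate
  exceeds baseline mean + k*SD (k = 2 by default), searched over the first
  400 ms after the event.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import signal, stats

from .session import SpikeTrain, Trial, TrialTable, WaveformTemplate

__all__ = [
    "PSTH",
    "ClassificationResult",
    "LatencyResult",
    "DiscriminationResult",
    "ClassificationThresholds",
    "spike_width",
    "classify_neuron",
    "baseline_stats",
    "psth",
    "window_rate",
    "compare_window_rates",
    "exact_sign_test",
    "sign_test_p",
    "response_latency",
    "discrimination_onset",
    "waveform_stability",
]


# ---------------------------------------------------------------------------
# binning helpers (half-open, exact integer counts)

def _bin_counts(offsets: np.ndarray, window: tuple[float, float], bin_width: float) -> np.ndarray:
    """Integer counts per half-open bin of ``[window[0], window[1])``."""
    n_bins = int(round((window[1] - window[0]) / bin_width))
    idx = np.floor((offsets - window[0]) / bin_width).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    return np.bincount(idx, minlength=n_bins)


def _aligned_offsets(
    spikes: SpikeTrain, trial: Trial, align: str, window: tuple[float, float]
) -> np.ndarray:
    ev = trial.event_time(align)
    if ev is None:
        return np.empty(0)
    times = spikes.spike_times
    lo = np.searchsorted(times, ev + window[0], side="left")
    hi = np.searchsorted(times, ev + window[1], side="left")
    return times[lo:hi] - ev


def _select(trials: TrialTable, align: str, condition: str | None) -> list[Trial]:
    out = [
        t
        for t in trials
        if t.valid
        and (condition is None or t.condition == condition)
        and t.event_time(align) is not None
    ]
    return out


# ---------------------------------------------------------------------------
# waveform width and classification

def spike_width(waveform: WaveformTemplate, prominence_frac: float = 0.1) -> float:
    """Trough-to-peak width (ms): time from the first negative local
    minimum to the next positive local maximum.

    ``prominence_frac`` (of the peak-to-peak amplitude) rejects extrema
    that are noise wiggles; set to 0 for a literal reading.
    """
    x = np.asarray(waveform.samples, dtype=float)
    if x.size < 3:
        raise ValueError("unmeasurable waveform: too few samples")
    prominence = prominence_frac * (x.max() - x.min()) if prominence_frac > 0 else None
    troughs, _ = signal.find_peaks(-x, prominence=prominence)
    troughs = [i for i in troughs if x[i] < 0]
    if not troughs:
        raise ValueError("unmeasurable waveform: no negative local minimum")
    i0 = troughs[0]
    peaks, _ = signal.find_peaks(x[i0:], prominence=prominence)
    peaks = [i0 + j for j in peaks if x[i0 + j] > 0]
    if not peaks:
        raise ValueError("unmeasurable waveform: no positive local maximum after trough")
    return (peaks[0] - i0) * waveform.sample_interval_ms


@dataclass(frozen=True)
class ClassificationThresholds:
    da_rate_range: tuple[float, float] = (1.0, 10.0)  # Hz
    da_min_width: float = 0.45  # ms
    snr_min_rate: float = 40.0  # Hz


@dataclass(frozen=True)
class ClassificationResult:
    neuron_id: str
    label: str  # DA | SNr | unclassified
    baseline_rate: float
    spike_width: float


def classify_neuron(
    baseline_rate: float,
    width: float,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    neuron_id: str = "",
) -> ClassificationResult:
    """Label a unit from baseline rate and spike width alone.

    DA: rate within [1, 10] Hz and width > 0.45 ms.
    SNr: rate > 40 Hz and width <= 0.45 ms.  Anything else: unclassified.
    """
    lo, hi = thresholds.da_rate_range
    if lo <= baseline_rate <= hi and width > thresholds.da_min_width:
        label = "DA"
    elif baseline_rate > thresholds.snr_min_rate and width <= thresholds.da_min_width:
        label = "SNr"
    else:
        label = "unclassified"
    return ClassificationResult(
        neuron_id=neuron_id, label=label, baseline_rate=baseline_rate, spike_width=width
    )


# ---------------------------------------------------------------------------
# baseline, PSTH, window rates

def baseline_stats(
    spikes: SpikeTrain,
    trials: TrialTable,
    baseline_window: tuple[float, float] = (-0.5, 0.0),
    bin_width: float = 0.1,
) -> tuple[float, float]:
    """(mean, SD) of per-trial-bin firing rates in a pre-FP window."""
    sel = _select(trials, "FP", None)
    if len(sel) < 10:
        raise ValueError(f"too few trials for baseline ({len(sel)} < 10)")
    rates = []
    for t in sel:
        offs = _aligned_offsets(spikes, t, "FP", baseline_window)
        counts = _bin_counts(offs, baseline_window, bin_width)
        rates.extend(counts / bin_width)
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0 or not np.any(rates):
        return (0.0, 0.0)
    return (float(rates.mean()), float(rates.std(ddof=1)))


@dataclass
class PSTH:
    """Event-aligned, trial-averaged firing rate for one trial selection."""

    align_event: str
    bin_width: float
    window: tuple[float, float]
    counts: np.ndarray  # integer spike counts per bin, summed over trials
    rates: np.ndarray  # Hz: counts / (n_trials * bin_width)
    n_trials: int
    condition: str | None = None

    @property
    def bin_starts(self) -> np.ndarray:
        return self.window[0] + np.arange(self.counts.size) * self.bin_width


def psth(
    spikes: SpikeTrain,
    trials: TrialTable,
    align: str = "CS",
    condition: str | None = None,
    bin_width: float = 0.01,
    window: tuple[float, float] = (-0.5, 1.0),
) -> PSTH:
    """rates[b] = total spikes in bin b across valid trials / (n * bin_width)."""
    sel = _select(trials, align, condition)
    if not sel:
        raise ValueError("empty trial selection")
    n_bins = int(round((window[1] - window[0]) / bin_width))
    counts = np.zeros(n_bins, dtype=int)
    for t in sel:
        offs = _aligned_offsets(spikes, t, align, window)
        counts += _bin_counts(offs, window, bin_width)
    rates = counts / (len(sel) * bin_width)
    return PSTH(
        align_event=align, bin_width=bin_width, window=window,
        counts=counts, rates=rates, n_trials=len(sel), condition=condition,
    )


def window_rate(
    spikes: SpikeTrain,
    trials: TrialTable,
    align: str,
    window: tuple[float, float],
    condition: str | None = None,
) -> np.ndarray:
    """Per-valid-trial firing rate (Hz) in ``[event+start, event+end)``."""
    if not window[0] < window[1]:
        raise ValueError("window start must precede end")
    sel = _select(trials, align, condition)
    if not sel:
        raise ValueError("empty trial selection")
    width = window[1] - window[0]
    return np.asarray(
        [_aligned_offsets(spikes, t, align, window).size / width for t in sel]
    )


# ---------------------------------------------------------------------------
# statistical tests

def sign_test_p(n_pos: int, n_neg: int, tail: str = "two_sided") -> float:
    """Exact binomial sign test on positive/negative counts (ties already
    dropped).  Two-sided p = 2 * min(tail probabilities), capped at 1; an
    empty sample reports p = 1 by convention.

    Computed in exact integer arithmetic so it agrees bit-for-bit with an
    exhaustive enumeration of sign patterns.
    """
    n = n_pos + n_neg
    if n == 0:
        return 1.0
    denom = 2**n
    ge = sum(comb(n, j) for j in range(n_pos, n + 1))  # P(X >= n_pos) * 2^n
    le = sum(comb(n, j) for j in range(0, n_pos + 1))  # P(X <= n_pos) * 2^n
    if tail == "greater":
        return ge / denom
    if tail == "less":
        return le / denom
    if tail == "two_sided":
        return min(denom, 2 * min(ge, le)) / denom
    raise ValueError(f"unknown tail {tail!r}")


def exact_sign_test(
    a: np.ndarray, b: np.ndarray | float = 0.0, tail: str = "two_sided"
) -> tuple[int, float]:
    """Sign test of paired samples (or of ``a`` against a scalar).

    Zero differences are dropped (n reduced accordingly).  Returns
    (number of positive differences, p).
    """
    diffs = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n_pos = int(np.sum(diffs > 0))
    n_neg = int(np.sum(diffs < 0))
    return n_pos, sign_test_p(n_pos, n_neg, tail=tail)


_ALT = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def compare_window_rates(
    values_a: np.ndarray,
    values_b,
    test: str = "wilcoxon_signed_rank",
    tail: str = "two_sided",
) -> tuple[float, float]:
    """Standard test contracts on per-trial (or per-neuron/session) rates.

    ``one_sample_t`` compares ``values_a`` against the scalar ``values_b``.
    Degenerate inputs (all ties / zero variance at equal means) report
    p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    alt = _ALT[tail]
    if test == "one_sample_t":
        if a.size < 5:
            raise ValueError(f"insufficient n for one_sample_t ({a.size} < 5)")
        if np.ptp(a) == 0:
            popmean = float(values_b)
            return (0.0, 1.0) if a[0] == popmean else (np.inf, 0.0)
        res = stats.ttest_1samp(a, popmean=float(values_b), alternative=alt)
        return float(res.statistic), float(res.pvalue)

    b = np.asarray(values_b, dtype=float)
    if test == "wilcoxon_signed_rank":
        if a.size != b.size:
            raise ValueError("paired test requires equal lengths")
        if a.size < 5:
            raise ValueError(f"insufficient n for wilcoxon ({a.size} < 5)")
        if np.all(a == b):
            return (0.0, 1.0)
        res = stats.wilcoxon(a, b, alternative=alt)
        return float(res.statistic), float(res.pvalue)
    if test == "welch_t":
        if a.size < 5 or b.size < 5:
            raise ValueError("insufficient n for welch_t")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            return (0.0, 1.0) if a[0] == b[0] else (np.inf, 0.0)
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alt)
        return float(res.statistic), float(res.pvalue)
    if test == "sign_test":
        if a.size != b.size:
            raise ValueError("paired test requires equal lengths")
        if a.size < 5:
            raise ValueError(f"insufficient n for sign_test ({a.size} < 5)")
        n_pos, p = exact_sign_test(a, b, tail=tail)
        return float(n_pos), p
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# latency and discrimination onset

@dataclass(frozen=True)
class LatencyResult:
    latency_ms: float | None
    baseline_mean: float
    baseline_sd: float
    criterion_k: float
    bin_width: float


def response_latency(
    spikes: SpikeTrain,
    trials: TrialTable,
    align: str = "CS",
    baseline: tuple[float, float] = (0.0, 0.0),
    bin_width: float = 0.01,
    criterion_k: float = 2.0,
    search_window: tuple[float, float] = (0.0, 0.4),
    condition: str | None = None,
) -> LatencyResult:
    """First bin whose across-trial mean rate exceeds baseline mean + k*SD.

    Undefined (``latency_ms=None``) if no bin in the search window crosses
    the criterion.  The search is capped at 400 ms post-event by default to
    avoid contamination by later task events.
    """
    mean, sd = baseline
    if sd < 0:
        raise ValueError("baseline SD must be >= 0")
    h = psth(spikes, trials, align=align, condition=condition,
             bin_width=bin_width, window=search_window)
    threshold = mean + criterion_k * sd
    above = h.rates > threshold
    if not np.any(above):
        return LatencyResult(None, mean, sd, criterion_k, bin_width)
    i = int(np.argmax(above))
    latency_ms = (search_window[0] + i * bin_width) * 1000.0
    return LatencyResult(latency_ms, mean, sd, criterion_k, bin_width)


@dataclass
class DiscriminationResult:
    p_values: np.ndarray
    alpha: float
    bin_width: float
    t_start: float  # s, time of the left edge of the first bin
    onsets_ms: dict[int, float | None]  # persistence (ms) -> onset (ms) or None
    n_neurons: int

    @property
    def onset_15ms(self):
        return self.onsets_ms.get(15)

    @property
    def onset_50ms(self):
        return self.onsets_ms.get(50)


def discrimination_onset(
    per_neuron_bin_rates_lr: np.ndarray,
    per_neuron_bin_rates_sr: np.ndarray,
    alpha: float = 0.05,
    bin_width: float = 0.01,
    persistence_ms: tuple[int, ...] = (15, 50),
    t_start: float = 0.0,
) -> DiscriminationResult:
    """Per-bin two-sided exact sign test across neurons on LR - SR rates,
    then the left edge of the earliest run of consecutive significant bins
    spanning strictly more than each persistence criterion.

    Inputs are (n_neurons, n_bins) arrays of per-neuron mean rates.
    """
    lr = np.asarray(per_neuron_bin_rates_lr, dtype=float)
    sr = np.asarray(per_neuron_bin_rates_sr, dtype=float)
    if lr.shape != sr.shape or lr.ndim != 2:
        raise ValueError("LR and SR rate arrays must both be (n_neurons, n_bins)")
    n_neurons, n_bins = lr.shape
    if n_neurons < 6:
        raise ValueError(
            f"underpowered: two-sided sign test needs >= 6 neurons to reach "
            f"p < 0.05, got {n_neurons}"
        )
    p_values = np.asarray(
        [exact_sign_test(lr[:, b], sr[:, b])[1] for b in range(n_bins)]
    )
    sig = p_values < alpha

    # consecutive runs of significant bins
    runs: list[tuple[int, int]] = []  # (start index, length)
    i = 0
    while i < n_bins:
        if sig[i]:
            j = i
            while j < n_bins and sig[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1

    onsets: dict[int, float | None] = {}
    for P in persistence_ms:
        onset = None
        for start, length in runs:
            if length * bin_width * 1000.0 > P:
                onset = (t_start + start * bin_width) * 1000.0
                break
        onsets[int(P)] = onset
    return DiscriminationResult(
        p_values=p_values, alpha=alpha, bin_width=bin_width, t_start=t_start,
        onsets_ms=onsets, n_neurons=n_neurons,
    )


# ---------------------------------------------------------------------------
# waveform stability

def waveform_stability(
    waveforms: list[WaveformTemplate],
    threshold: float = 0.95,
    resample: bool = True,
) -> tuple[np.ndarray, bool]:
    """Pairwise Pearson correlation of peak-normalized templates.

    ``stable`` iff the minimum pairwise r is at least ``threshold``.
    Templates of unequal length are linearly resampled to the longest
    (disable with ``resample=False`` to make a length mismatch an error).
    """
    if len(waveforms) < 2:
        raise ValueError("need at least two templates")
    lengths = {np.asarray(w.samples).size for w in waveforms}
    if len(lengths) > 1 and not resample:
        raise ValueError("templates differ in length and resampling is disabled")
    n = max(lengths)
    normed = []
    for w in waveforms:
        x = np.asarray(w.samples, dtype=float)
        if x.size != n:
            x = np.interp(np.linspace(0, x.size - 1, n), np.arange(x.size), x)
        peak = np.max(np.abs(x))
        normed.append(x / peak if peak > 0 else x)
    m = len(normed)
    r = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            r[i, j] = r[j, i] = float(np.corrcoef(normed[i], normed[j])[0, 1])
    off_diag = r[~np.eye(m, dtype=bool)]
    return r, bool(off_diag.min() >= threshold)
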