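"""Conditioned-licking quantification, behavioral comparisons, reversal
learning summaries, and SC-inactivation contrasts.

Licking is binned at 0.1 s by default and quantified in a CS-onset-aligned
window: 0-1.3 s for conditioned-response summaries, 0-0.7 s for LR - SR
inactivation contrasts (no reward event falls in 0-0.7 s under either CS
duration).  Baseline is the 1 s before CS onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session import LickRecord, Session, Trial, TrialTable
from .spikes import compare_window_rates

__all__ = [
    "LickRateProfile",
    "CRSummary",
    "lick_rate_profile",
    "cr_rate",
    "cr_rates_per_trial",
    "cr_summary",
    "test_cr_vs_baseline",
    "test_lr_vs_sr_sessions",
    "test_affected_vs_intact",
    "inactivation_effect",
    "reversal_curve",
    "ReversalCurve",
]

CR_WINDOW = (0.0, 1.3)
INACTIVATION_WINDOW = (0.0, 0.7)
BASELINE_WINDOW = (-1.0, 0.0)


def _select(trials: TrialTable, condition: str | None, epoch: str | None = None) -> list[Trial]:
    return [
        t for t in trials
        if t.valid
        and (condition is None or t.condition == condition)
        and (epoch is None or t.epoch == epoch)
    ]


def _count_in(licks: np.ndarray, lo: float, hi: float) -> int:
    return int(np.searchsorted(licks, hi, side="left") - np.searchsorted(licks, lo, side="left"))


@dataclass
class LickRateProfile:
    """CS-onset-aligned, trial-averaged lick rate for one trial selection."""

    bin_width: float
    window: tuple[float, float]
    counts: np.ndarray  # integer lick counts per bin, summed over trials
    rates: np.ndarray  # licks/s
    n_trials: int
    condition: str | None = None

    @property
    def bin_starts(self) -> np.ndarray:
        return self.window[0] + np.arange(self.counts.size) * self.bin_width


def lick_rate_profile(
    licks: LickRecord,
    trials: TrialTable,
    condition: str | None = None,
    bin_width: float = 0.1,
    window: tuple[float, float] = (-1.0, 3.5),
    epoch: str | None = None,
) -> LickRateProfile:
    """Per-bin lick count across valid trials / (n_trials * bin_width)."""
    sel = _select(trials, condition, epoch)
    if not sel:
        raise ValueError("empty trial selection")
    n_bins = int(round((window[1] - window[0]) / bin_width))
    counts = np.zeros(n_bins, dtype=int)
    lt = np.asarray(licks.lick_times, dtype=float)
    for t in sel:
        offs = lt[
            np.searchsorted(lt, t.cs_onset + window[0], side="left"):
            np.searchsorted(lt, t.cs_onset + window[1], side="left")
        ] - t.cs_onset
        idx = np.floor((offs - window[0]) / bin_width).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        counts += np.bincount(idx, minlength=n_bins)
    rates = counts / (len(sel) * bin_width)
    return LickRateProfile(
        bin_width=bin_width, window=window, counts=counts, rates=rates,
        n_trials=len(sel), condition=condition,
    )


def cr_rates_per_trial(
    licks: LickRecord,
    trials: TrialTable,
    condition: str | None = None,
    window: tuple[float, float] = CR_WINDOW,
    epoch: str | None = None,
) -> np.ndarray:
    """Per-valid-trial lick rate in ``[cs_onset+w0, cs_onset+w1)``."""
    if not window[0] < window[1]:
        raise ValueError("window start must precede end")
    sel = _select(trials, condition, epoch)
    if not sel:
        raise ValueError("empty trial selection")
    lt = np.asarray(licks.lick_times, dtype=float)
    width = window[1] - window[0]
    return np.asarray(
        [_count_in(lt, t.cs_onset + window[0], t.cs_onset + window[1]) / width for t in sel]
    )


def cr_rate(
    licks: LickRecord,
    trials: TrialTable,
    condition: str | None = None,
    window: tuple[float, float] = CR_WINDOW,
    epoch: str | None = None,
) -> float:
    """Session conditioned-response rate: mean of per-trial CS-window rates.

    Computed as total count / (n_trials * width), which equals the mean of
    per-trial rates exactly and is invariant to trial order.
    """
    if not window[0] < window[1]:
        raise ValueError("window start must precede end")
    sel = _select(trials, condition, epoch)
    if not sel:
        raise ValueError("empty trial selection")
    lt = np.asarray(licks.lick_times, dtype=float)
    total = sum(_count_in(lt, t.cs_onset + window[0], t.cs_onset + window[1]) for t in sel)
    return total / (len(sel) * (window[1] - window[0]))


@dataclass(frozen=True)
class CRSummary:
    """Per-session licking summary in a CS-aligned window."""

    session_id: str
    window: tuple[float, float]
    rate_lr: float
    rate_sr: float

    @property
    def lr_minus_sr(self) -> float:
        return self.rate_lr - self.rate_sr


def cr_summary(
    session_or_licks,
    trials: TrialTable | None = None,
    window: tuple[float, float] = INACTIVATION_WINDOW,
    epoch: str | None = None,
    session_id: str = "",
) -> CRSummary:
    """CRSummary from a :class:`Session` (or a licks+trials pair)."""
    if isinstance(session_or_licks, Session):
        licks = session_or_licks.licks
        trials = session_or_licks.trials
        session_id = session_id or session_or_licks.metadata.date
    else:
        licks = session_or_licks
        if trials is None:
            raise ValueError("trials required when passing a LickRecord")
    return CRSummary(
        session_id=session_id,
        window=window,
        rate_lr=cr_rate(licks, trials, "LR", window, epoch),
        rate_sr=cr_rate(licks, trials, "SR", window, epoch),
    )


# ---------------------------------------------------------------------------
# tests

def test_cr_vs_baseline(
    licks: LickRecord,
    trials: TrialTable,
    condition: str,
    cs_window: tuple[float, float] = CR_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> tuple[float, float]:
    """One-tailed paired t test of CS-window vs pre-CS baseline lick rates.

    Direction: CS > baseline.  If every pair is tied the boundary value
    (t = 0, p = 0.5) is reported.
    """
    cs = cr_rates_per_trial(licks, trials, condition, cs_window)
    bl = cr_rates_per_trial(licks, trials, condition, baseline_window)
    if cs.size < 5:
        raise ValueError(f"insufficient n ({cs.size} < 5)")
    if np.all(cs == bl):
        return (0.0, 0.5)
    res = stats.ttest_rel(cs, bl, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def test_lr_vs_sr_sessions(
    session_rates_lr, session_rates_sr
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank on paired per-session LR vs SR rates.

    Identical lists report (0, 1) -- the all-ties convention.
    """
    a = np.asarray(session_rates_lr, dtype=float)
    b = np.asarray(session_rates_sr, dtype=float)
    if a.size != b.size:
        raise ValueError("paired lists must have equal lengths")
    return compare_window_rates(a, b, test="wilcoxon_signed_rank", tail="two_sided")


def test_affected_vs_intact(rates_affected, rates_intact) -> tuple[float, float]:
    """Two-sided Welch t-test on independent per-session rate samples."""
    return compare_window_rates(
        np.asarray(rates_affected, dtype=float),
        np.asarray(rates_intact, dtype=float),
        test="welch_t",
        tail="two_sided",
    )


def inactivation_effect(
    sessions_before: list[CRSummary], sessions_during: list[CRSummary]
) -> dict:
    """Paired before/during inactivation contrast on LR - SR licking.

    Reports (i) a two-sided Wilcoxon signed-rank on the before vs during
    LR - SR differences and (ii) a one-sample t of the during differences
    against zero.  Degenerate zero-variance during samples set the
    ``no_variance`` flag (p reported as NaN).
    """
    if len(sessions_before) != len(sessions_during):
        raise ValueError("before/during summaries must be paired")
    n = len(sessions_before)
    if n < 5:
        raise ValueError(f"insufficient n ({n} < 5)")
    before = np.asarray([s.lr_minus_sr for s in sessions_before])
    during = np.asarray([s.lr_minus_sr for s in sessions_during])
    w_stat, w_p = compare_window_rates(before, during, test="wilcoxon_signed_rank")
    no_variance = bool(np.ptp(during) == 0)
    if no_variance:
        t_stat, t_p = (np.nan, np.nan)
    else:
        res = stats.ttest_1samp(during, popmean=0.0)
        t_stat, t_p = float(res.statistic), float(res.pvalue)
    return {
        "n": n,
        "before_mean": float(before.mean()),
        "during_mean": float(during.mean()),
        "wilcoxon_before_vs_during": {"statistic": w_stat, "p": w_p},
        "one_sample_t_during_vs_zero": {"statistic": t_stat, "p": t_p},
        "no_variance": no_variance,
    }


# ---------------------------------------------------------------------------
# reversal learning

@dataclass
class ReversalCurve:
    table: pd.DataFrame  # day, upper_rate, lower_rate, assignment_upper
    crossover_days: list[int | None]  # one entry per switch
    switch_days: list[int]

    @property
    def crossover_day(self) -> int | None:
        return self.crossover_days[0] if self.crossover_days else None


def reversal_curve(
    daily_sessions: list[Session],
    switch_days: list[int] | None = None,
    window: tuple[float, float] = CR_WINDOW,
    sustain_days: int = 2,
) -> ReversalCurve:
    """Per-day CS-window lick rate grouped by screen position (upper/lower),
    plus, for each switch, the first post-switch day on which the position
    ordering inverts and stays inverted for ``sustain_days`` consecutive
    days (None if it never does).

    Sessions must carry the CS-position -> reward assignment (the
    ``assignment_upper`` metadata entry, or derivable from trial labels).
    """
    rows = []
    inferred_switches = []
    prev_assign = None
    for i, s in enumerate(daily_sessions):
        assign = s.metadata.extra.get("assignment_upper")
        if assign is None:
            uppers = {t.condition for t in s.trials if t.cs_position[1] >= 0}
            if len(uppers) != 1:
                raise ValueError(f"session {i}: cannot derive CS-position assignment")
            assign = uppers.pop()
        day = s.metadata.extra.get("day", i + 1)
        upper = [t for t in s.trials if t.valid and t.cs_position[1] >= 0]
        lower = [t for t in s.trials if t.valid and t.cs_position[1] < 0]
        if not upper or not lower:
            raise ValueError(f"session {i}: missing upper or lower position trials")
        lt = np.asarray(s.licks.lick_times, dtype=float)
        width = window[1] - window[0]

        def _rate(ts):
            return float(
                np.mean(
                    [
                        _count_in(lt, t.cs_onset + window[0], t.cs_onset + window[1]) / width
                        for t in ts
                    ]
                )
            )

        rows.append(
            {
                "day": int(day),
                "upper_rate": _rate(upper),
                "lower_rate": _rate(lower),
                "assignment_upper": assign,
            }
        )
        if prev_assign is not None and assign != prev_assign:
            inferred_switches.append(int(day))
        prev_assign = assign

    table = pd.DataFrame(rows).sort_values("day").reset_index(drop=True)
    switches = list(switch_days) if switch_days is not None else inferred_switches

    crossovers: list[int | None] = []
    for sw in switches:
        pre = table[table["day"] < sw]
        if pre.empty:
            crossovers.append(None)
            continue
        pre_row = pre.iloc[-1]
        pre_sign = np.sign(pre_row["upper_rate"] - pre_row["lower_rate"])
        post = table[table["day"] >= sw].reset_index(drop=True)
        inverted = (np.sign(post["upper_rate"] - post["lower_rate"]) == -pre_sign).to_numpy()
        found = None
        for j in range(len(post)):
            run = inverted[j : j + sustain_days]
            if run.size == sustain_days and run.all():
                found = int(post.loc[j, "day"])
                break
        crossovers.append(found)
    return ReversalCurve(table=table, crossover_days=crossovers, switch_days=switches)
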