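"""Saccade scoring, contrast-unit conversion, d'=2 contrast-threshold
estimation, and deficit-map assembly.

The d' = 2 <-> proportion-correct mapping uses the equal-variance yes/no
approximation with an unbiased criterion: p(correct) = Phi(d'/2), i.e.
0.8413 at d' = 2.  The criterion probability is a parameter so an mAFC
mapping can be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .session import PsychometricRecord

__all__ = [
    "ContrastPair",
    "SaccadeWindowRule",
    "PsychometricFit",
    "DeficitMap",
    "michelson_to_weber",
    "weber_to_michelson",
    "polar_to_cartesian",
    "saccade_correct",
    "fit_psychometric",
    "build_deficit_map",
    "DPRIME2_CRITERION_P",
]

#: p(correct) at d' = 2 under the equal-variance unbiased-criterion model.
DPRIME2_CRITERION_P = float(stats.norm.cdf(1.0))


def michelson_to_weber(m: float, background: float = 1.0) -> float:
    """Weber contrast of a target brighter than the background.

    With Michelson contrast m, the target luminance on background Lb is
    L = Lb*(1+m)/(1-m), so Weber contrast (L-Lb)/Lb = 2m/(1-m); the
    background cancels.
    """
    if not 0 <= m < 1:
        raise ValueError(f"Michelson contrast must be in [0, 1), got {m}")
    if background <= 0:
        raise ValueError("background luminance must be positive")
    return 2.0 * m / (1.0 - m)


def weber_to_michelson(w: float) -> float:
    """Inverse of :func:`michelson_to_weber`: m = w / (2 + w)."""
    if w < 0:
        raise ValueError(f"Weber contrast must be >= 0, got {w}")
    return w / (2.0 + w)


def polar_to_cartesian(ecc: float, direction_deg: float) -> tuple[float, float]:
    th = math.radians(direction_deg)
    return (ecc * math.cos(th), ecc * math.sin(th))


@dataclass(frozen=True)
class ContrastPair:
    michelson: float
    background: float = 1.0

    @property
    def weber(self) -> float:
        return michelson_to_weber(self.michelson, self.background)


@dataclass(frozen=True)
class SaccadeWindowRule:
    """Circular scoring window around a target position.

    Two radius formulas are implemented because both appear in the task
    descriptions; ``sine_half_angle`` (radius = ecc * sin(angle/2), the
    half-distance between neighboring targets) is the default.  A
    subject-specific ``radius_override`` takes precedence over either.
    """

    eccentricity: float
    neighbor_angle_deg: float
    formula_variant: str = "sine_half_angle"  # or "half_sine"
    radius_override: float | None = None

    @property
    def radius(self) -> float:
        if self.radius_override is not None:
            return self.radius_override
        a = math.radians(self.neighbor_angle_deg)
        if self.formula_variant == "sine_half_angle":
            r = self.eccentricity * math.sin(a / 2.0)
        elif self.formula_variant == "half_sine":
            r = self.eccentricity * math.sin(a) / 2.0
        else:
            raise ValueError(f"unknown formula variant {self.formula_variant!r}")
        if r <= 0:
            raise ValueError("window radius must be positive")
        return r


def saccade_correct(
    endpoint: tuple[float, float] | None,
    target: tuple[float, float],
    rule: SaccadeWindowRule,
) -> bool:
    """True iff the saccade endpoint lands within the scoring circle.

    ``target`` is polar (eccentricity deg, direction deg); ``endpoint`` is
    Cartesian degrees.  A missing endpoint (no response within 1 s) is
    scored incorrect.
    """
    if endpoint is None:
        return False
    tx, ty = polar_to_cartesian(*target)
    return math.hypot(endpoint[0] - tx, endpoint[1] - ty) <= rule.radius


# ---------------------------------------------------------------------------
# psychometric fitting

@dataclass(frozen=True)
class PsychometricFit:
    location: tuple[float, float] | None
    threshold_michelson: float
    slope: float  # 1/sigma in log-contrast units
    guess_rate: float
    lapse: float
    n_trials: int
    converged: bool

    @property
    def threshold_weber(self) -> float:
        return michelson_to_weber(self.threshold_michelson)


def _predicted_p(logc, mu, sigma, guess, lapse):
    return guess + (1.0 - guess - lapse) * stats.norm.cdf((logc - mu) / sigma)


def fit_psychometric(
    points: list[tuple[float, int, int]],
    guess_rate: float = 0.0,
    criterion_p: float = DPRIME2_CRITERION_P,
    lapse_max: float = 0.05,
    location: tuple[float, float] | None = None,
) -> PsychometricFit:
    """Maximum-likelihood cumulative Gaussian in log contrast.

    ``points`` are (contrast, n, n_correct) triples.  The guess rate is
    fixed; the lapse rate is free on [0, lapse_max].  The threshold is the
    contrast at which the predicted proportion correct equals
    ``criterion_p`` (the d' = 2 criterion).  ``converged`` is False when
    the optimizer fails or the threshold falls outside the tested contrast
    range (it is then clamped to the range boundary).
    """
    if len({c for c, _, _ in points}) < 3:
        raise ValueError("need at least 3 distinct contrasts")
    c = np.asarray([p[0] for p in points], dtype=float)
    n = np.asarray([p[1] for p in points], dtype=int)
    k = np.asarray([p[2] for p in points], dtype=int)
    if np.any(k > n) or np.any(n <= 0):
        raise ValueError("n_correct must satisfy 0 <= n_correct <= n, n > 0")
    total = int(n.sum())
    if total < 30:
        raise ValueError(f"need at least 30 trials, got {total}")
    frac = k / n
    if np.all(k == n) or np.all(k == 0):
        raise ValueError("degenerate data: responses identical at every contrast")

    logc = np.log(c)

    def nll(theta):
        mu, log_sigma, lapse = theta
        p = _predicted_p(logc, mu, np.exp(log_sigma), guess_rate, lapse)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -float(np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))

    x0 = np.array([float(np.median(logc)), 0.0, min(0.01, lapse_max)])
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B",
        bounds=[(logc.min() - 5, logc.max() + 5), (-4.0, 3.0), (0.0, lapse_max)],
    )
    mu, log_sigma, lapse = res.x
    sigma = float(np.exp(log_sigma))
    converged = bool(res.success)
    # flat fitted curve: the criterion crossing is undefined within the range
    p_span = _predicted_p(logc, mu, sigma, guess_rate, lapse)
    if float(p_span.max() - p_span.min()) < 0.1:
        converged = False

    q = (criterion_p - guess_rate) / (1.0 - guess_rate - lapse)
    if not 0 < q < 1:
        threshold = float(c.max())
        converged = False
    else:
        log_thr = mu + sigma * stats.norm.ppf(q)
        threshold = float(np.exp(log_thr))
        if not c.min() <= threshold <= c.max():
            threshold = float(np.clip(threshold, c.min(), c.max()))
            converged = False
    return PsychometricFit(
        location=location,
        threshold_michelson=threshold,
        slope=1.0 / sigma,
        guess_rate=guess_rate,
        lapse=float(lapse),
        n_trials=total,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# deficit maps

@dataclass
class DeficitMap:
    fits: dict[tuple[float, float], PsychometricFit]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (ecc, d), f in sorted(self.fits.items()):
            rows.append(
                {
                    "ecc_deg": ecc,
                    "dir_deg": d,
                    "threshold_michelson": f.threshold_michelson,
                    "threshold_weber": f.threshold_weber,
                    "n": f.n_trials,
                    "converged": f.converged,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["ecc_deg", "dir_deg", "threshold_michelson",
                     "threshold_weber", "n", "converged"],
        )


def build_deficit_map(
    psychometrics: PsychometricRecord,
    grid: list[tuple[float, float]],
    neighbor_angle_deg: float,
    formula_variant: str = "sine_half_angle",
    radius_override: float | None = None,
    guess_rate: float = 0.0,
    criterion_p: float = DPRIME2_CRITERION_P,
) -> DeficitMap:
    """Score every saccade trial, aggregate per grid cell x contrast, and
    fit a threshold per cell.

    Raises if any grid cell has no trials (named in the error).
    """
    by_cell: dict[tuple[float, float], dict[float, list[bool]]] = {
        tuple(cell): {} for cell in grid
    }
    for t in psychometrics:
        cell = tuple(t.target_position)
        if cell not in by_cell:
            continue
        rule = SaccadeWindowRule(
            eccentricity=cell[0],
            neighbor_angle_deg=neighbor_angle_deg,
            formula_variant=formula_variant,
            radius_override=radius_override,
        )
        ok = t.responded_within_1s and saccade_correct(t.saccade_endpoint, cell, rule)
        by_cell[cell].setdefault(t.michelson_contrast, []).append(bool(ok))

    fits = {}
    for cell, per_contrast in by_cell.items():
        if not per_contrast:
            raise ValueError(f"empty cell: no trials at (ecc={cell[0]}, dir={cell[1]})")
        points = [
            (c, len(v), int(sum(v))) for c, v in sorted(per_contrast.items())
        ]
        fits[cell] = fit_psychometric(
            points, guess_rate=guess_rate, criterion_p=criterion_p, location=cell
        )
    return DeficitMap(fits=fits)
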