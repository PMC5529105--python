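"""Shared data model for a recording/behavior session and its on-disk bundle.

A session bundle is a directory of plain-text files::

    trials.csv          trial_id,condition,field,epoch,fp_onset,cs_onset,
                        cs_offset,reward_time,reward_volume,ecc_deg,dir_deg,valid
    licks.csv           lick_time
    spikes/<id>.csv     spike_time
    waveforms/<id>.json {"sample_interval_ms": ..., "epochs": [{"label", "samples"}]}
    psychometrics.csv   ecc_deg,dir_deg,contrast,endpoint_x,endpoint_y,responded
    metadata.json       subject, date, field, inactivation, extra

All times are seconds on a single session clock; event alignment is done
downstream by subtraction.  Floats are serialized at 6 decimal places
(microsecond resolution), which exceeds every analysis bin width, so a
round-trip through disk is lossless for values generated by this package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trial",
    "TrialTable",
    "SpikeTrain",
    "WaveformTemplate",
    "LickRecord",
    "PsychometricTrial",
    "PsychometricRecord",
    "SessionMetadata",
    "Session",
    "SessionError",
    "MalformedBundleError",
    "InvalidSpikeTrainError",
    "InvalidTrialTableError",
    "SessionValidationError",
    "read_session",
    "write_session",
    "validate_session",
    "LR_REWARD_DELAY",
    "SR_REWARD_DELAY",
    "CS_DURATIONS",
]

CONDITIONS = ("LR", "SR")
FIELDS = ("affected", "intact")
EPOCHS = ("pre_inactivation", "during_inactivation", "none")

#: Large reward is delivered 1.3 s after CS onset (i.e. during the CS).
LR_REWARD_DELAY = 1.3
#: Small reward is delivered 1.5 s after CS offset.
SR_REWARD_DELAY = 1.5
#: Admissible CS presentation durations (s).
CS_DURATIONS = (1.0, 1.7)

_TIME_TOL = 1e-6  # serialization resolution


class SessionError(ValueError):
    """Base class for session model errors."""


class MalformedBundleError(SessionError):
    pass


class InvalidSpikeTrainError(SessionError):
    pass


class InvalidTrialTableError(SessionError):
    pass


class SessionValidationError(SessionError):
    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            "session failed validation:\n" + "\n".join(f"  - {v}" for v in violations)
        )


def _round6(x: float) -> float:
    return round(float(x), 6)


@dataclass(frozen=True)
class Trial:
    """One Pavlovian trial: event times on the session clock plus labels.

    ``reward_time`` is stored explicitly even though it is derivable from the
    condition, so that alternative schedules can be represented.  ``valid``
    is a stored flag (fixation maintained until CS offset); invalid trials
    are excluded from every downstream statistic.
    """

    trial_id: int
    condition: str  # "LR" | "SR"
    fp_onset: float
    cs_onset: float
    cs_offset: float
    reward_time: float | None
    reward_volume: float
    cs_position: tuple[float, float]  # (eccentricity deg, direction deg)
    field: str = "intact"  # "affected" | "intact"
    epoch: str = "none"
    valid: bool = True

    def event_time(self, align: str) -> float | None:
        if align == "FP":
            return self.fp_onset
        if align == "CS":
            return self.cs_onset
        if align == "RW":
            return self.reward_time
        raise ValueError(f"unknown alignment event {align!r}")


class TrialTable:
    """Ordered collection of :class:`Trial` with selection helpers."""

    def __init__(self, trials: Sequence[Trial] = ()):
        self._trials: list[Trial] = list(trials)

    def __len__(self) -> int:
        return len(self._trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self._trials)

    def __getitem__(self, i):
        return self._trials[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, TrialTable) and self._trials == other._trials

    def select(
        self,
        condition: str | None = None,
        epoch: str | None = None,
        valid_only: bool = True,
        with_reward: bool = False,
    ) -> "TrialTable":
        out = []
        for t in self._trials:
            if valid_only and not t.valid:
                continue
            if condition is not None and t.condition != condition:
                continue
            if epoch is not None and t.epoch != epoch:
                continue
            if with_reward and t.reward_time is None:
                continue
            out.append(t)
        return TrialTable(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self._trials:
            rows.append(
                {
                    "trial_id": t.trial_id,
                    "condition": t.condition,
                    "field": t.field,
                    "epoch": t.epoch,
                    "fp_onset": t.fp_onset,
                    "cs_onset": t.cs_onset,
                    "cs_offset": t.cs_offset,
                    "reward_time": t.reward_time,
                    "reward_volume": t.reward_volume,
                    "ecc_deg": t.cs_position[0],
                    "dir_deg": t.cs_position[1],
                    "valid": t.valid,
                }
            )
        cols = [
            "trial_id", "condition", "field", "epoch", "fp_onset", "cs_onset",
            "cs_offset", "reward_time", "reward_volume", "ecc_deg", "dir_deg",
            "valid",
        ]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class SpikeTrain:
    """Spike times (s, session clock) of one unit; strictly increasing."""

    neuron_id: str
    spike_times: np.ndarray

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpikeTrain)
            and self.neuron_id == other.neuron_id
            and np.array_equal(self.spike_times, other.spike_times)
        )

    def __len__(self) -> int:
        return self.spike_times.size


@dataclass
class WaveformTemplate:
    """Averaged spike waveform; amplitudes in arbitrary (possibly normalized) units."""

    samples: np.ndarray
    sample_interval_ms: float
    epoch_label: str = "avg"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WaveformTemplate)
            and self.epoch_label == other.epoch_label
            and self.sample_interval_ms == other.sample_interval_ms
            and np.array_equal(self.samples, other.samples)
        )


@dataclass
class LickRecord:
    """Lick-event times (s, session clock); a single event stream."""

    lick_times: np.ndarray

    def __post_init__(self):
        self.lick_times = np.asarray(self.lick_times, dtype=float)

    def __eq__(self, other) -> bool:
        return isinstance(other, LickRecord) and np.array_equal(
            self.lick_times, other.lick_times
        )

    def __len__(self) -> int:
        return self.lick_times.size


@dataclass(frozen=True)
class PsychometricTrial:
    target_position: tuple[float, float]  # (ecc deg, direction deg)
    michelson_contrast: float
    saccade_endpoint: tuple[float, float] | None  # (x deg, y deg)
    responded_within_1s: bool


@dataclass
class PsychometricRecord:
    trials: list[PsychometricTrial] = dc_field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __eq__(self, other) -> bool:
        return isinstance(other, PsychometricRecord) and self.trials == other.trials

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            ex, ey = (t.saccade_endpoint if t.saccade_endpoint is not None else (None, None))
            rows.append(
                {
                    "ecc_deg": t.target_position[0],
                    "dir_deg": t.target_position[1],
                    "contrast": t.michelson_contrast,
                    "endpoint_x": ex,
                    "endpoint_y": ey,
                    "responded": t.responded_within_1s,
                }
            )
        cols = ["ecc_deg", "dir_deg", "contrast", "endpoint_x", "endpoint_y", "responded"]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class SessionMetadata:
    subject: str = "synthetic"
    date: str = "1970-01-01"
    field: str = "affected"
    inactivation: bool = False
    extra: dict = dc_field(default_factory=dict)


@dataclass
class Session:
    trials: TrialTable
    spikes: dict[str, SpikeTrain]
    waveforms: dict[str, list[WaveformTemplate]]
    licks: LickRecord
    psychometrics: PsychometricRecord | None = None
    metadata: SessionMetadata = dc_field(default_factory=SessionMetadata)


# ---------------------------------------------------------------------------
# validation

def _finite(x) -> bool:
    try:
        return x is not None and math.isfinite(float(x))
    except (TypeError, ValueError):
        return False


def validate_session(session: Session) -> list[str]:
    """Check every type invariant; return a description per violation.

    Total: reports rather than raises, for arbitrary field values.
    """
    v: list[str] = []
    try:
        for t in session.trials:
            tid = getattr(t, "trial_id", "?")
            if t.condition not in CONDITIONS:
                v.append(f"trial {tid}: unknown condition {t.condition!r}")
                continue
            if t.field not in FIELDS:
                v.append(f"trial {tid}: unknown field {t.field!r}")
            if t.epoch not in EPOCHS:
                v.append(f"trial {tid}: unknown epoch {t.epoch!r}")
            if not (_finite(t.fp_onset) and _finite(t.cs_onset) and _finite(t.cs_offset)):
                v.append(f"trial {tid}: non-finite event time")
                continue
            if not (t.fp_onset < t.cs_onset < t.cs_offset):
                v.append(
                    f"trial {tid}: event order violated "
                    f"(fp={t.fp_onset}, cs_on={t.cs_onset}, cs_off={t.cs_offset})"
                )
            dur = t.cs_offset - t.cs_onset
            if not any(abs(dur - d) <= 1e-5 for d in CS_DURATIONS):
                v.append(f"trial {tid}: CS duration {dur:.6f} s not in {CS_DURATIONS}")
            if t.reward_time is not None and _finite(t.reward_time):
                if t.condition == "LR":
                    expect = t.cs_onset + LR_REWARD_DELAY
                    if abs(t.reward_time - expect) > 1e-5:
                        v.append(
                            f"trial {tid}: LR reward_time {t.reward_time:.6f} != "
                            f"cs_onset + {LR_REWARD_DELAY} ({expect:.6f})"
                        )
                else:
                    expect = t.cs_offset + SR_REWARD_DELAY
                    if abs(t.reward_time - expect) > 1e-5:
                        v.append(
                            f"trial {tid}: SR reward_time {t.reward_time:.6f} != "
                            f"cs_offset + {SR_REWARD_DELAY} ({expect:.6f})"
                        )
            if _finite(t.reward_volume) and t.reward_volume < 0:
                v.append(f"trial {tid}: negative reward volume")
            ecc = t.cs_position[0]
            if _finite(ecc) and ecc <= 0:
                v.append(f"trial {tid}: CS eccentricity must be > 0")
    except Exception as exc:  # pragma: no cover - defensive
        v.append(f"trial table unreadable: {exc!r}")

    try:
        for nid, st in session.spikes.items():
            times = np.asarray(st.spike_times, dtype=float)
            if times.size and times[0] < 0:
                v.append(f"neuron {nid}: negative spike time")
            if times.size > 1 and not np.all(np.diff(times) > 0):
                v.append(f"neuron {nid}: spike times not strictly increasing")
            if nid not in session.waveforms or not session.waveforms[nid]:
                v.append(f"neuron {nid}: no waveform template")
    except Exception as exc:  # pragma: no cover
        v.append(f"spike map unreadable: {exc!r}")

    try:
        for nid, wfs in session.waveforms.items():
            if nid not in session.spikes:
                v.append(f"waveform {nid}: no matching spike train")
            for w in wfs:
                if np.asarray(w.samples).size < 16:
                    v.append(f"waveform {nid}/{w.epoch_label}: fewer than 16 samples")
                if not (_finite(w.sample_interval_ms) and w.sample_interval_ms > 0):
                    v.append(f"waveform {nid}/{w.epoch_label}: non-positive sample interval")
    except Exception as exc:  # pragma: no cover
        v.append(f"waveform map unreadable: {exc!r}")

    try:
        lt = np.asarray(session.licks.lick_times, dtype=float)
        if lt.size and lt[0] < 0:
            v.append("licks: negative lick time")
        if lt.size > 1 and not np.all(np.diff(lt) >= 0):
            v.append("licks: lick times not increasing")
    except Exception as exc:  # pragma: no cover
        v.append(f"lick record unreadable: {exc!r}")

    if session.psychometrics is not None:
        try:
            for i, p in enumerate(session.psychometrics):
                if not (0 < p.michelson_contrast < 1):
                    v.append(f"psychometric trial {i}: contrast outside (0,1)")
                if p.target_position[0] <= 0:
                    v.append(f"psychometric trial {i}: eccentricity must be > 0")
        except Exception as exc:  # pragma: no cover
            v.append(f"psychometric record unreadable: {exc!r}")

    dur = None
    try:
        dur = session.metadata.extra.get("duration_s")
    except Exception:
        dur = None
    if _finite(dur):
        events = []
        for t in session.trials:
            events.extend([t.fp_onset, t.cs_offset] + ([t.reward_time] if t.reward_time else []))
        for st in session.spikes.values():
            if len(st):
                events.append(float(st.spike_times[-1]))
        if len(session.licks):
            events.append(float(session.licks.lick_times[-1]))
        if events and max(events) > float(dur) + _TIME_TOL:
            v.append(f"event time {max(events):.6f} exceeds session duration {dur}")
    return v


# ---------------------------------------------------------------------------
# serialization

def _fmt(x: float | None) -> str:
    return "" if x is None else f"{float(x):.6f}"


def write_session(session: Session, path: str | Path) -> None:
    """Write a session bundle with deterministic byte layout.

    Raises :class:`SessionValidationError` instead of writing an invalid
    session.
    """
    violations = validate_session(session)
    if violations:
        raise SessionValidationError(violations)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "spikes").mkdir(exist_ok=True)
    (path / "waveforms").mkdir(exist_ok=True)

    lines = [
        "trial_id,condition,field,epoch,fp_onset,cs_onset,cs_offset,"
        "reward_time,reward_volume,ecc_deg,dir_deg,valid"
    ]
    for t in session.trials:
        lines.append(
            ",".join(
                [
                    str(t.trial_id),
                    t.condition,
                    t.field,
                    t.epoch,
                    _fmt(t.fp_onset),
                    _fmt(t.cs_onset),
                    _fmt(t.cs_offset),
                    _fmt(t.reward_time),
                    _fmt(t.reward_volume),
                    _fmt(t.cs_position[0]),
                    _fmt(t.cs_position[1]),
                    "true" if t.valid else "false",
                ]
            )
        )
    (path / "trials.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    lick_lines = ["lick_time"] + [_fmt(x) for x in session.licks.lick_times]
    (path / "licks.csv").write_text("\n".join(lick_lines) + "\n", encoding="utf-8")

    for nid in sorted(session.spikes):
        st = session.spikes[nid]
        sl = ["spike_time"] + [_fmt(x) for x in st.spike_times]
        (path / "spikes" / f"{nid}.csv").write_text("\n".join(sl) + "\n", encoding="utf-8")

    for nid in sorted(session.waveforms):
        wfs = session.waveforms[nid]
        payload = {
            "sample_interval_ms": _round6(wfs[0].sample_interval_ms),
            "epochs": [
                {"label": w.epoch_label, "samples": [_round6(s) for s in w.samples]}
                for w in wfs
            ],
        }
        (path / "waveforms" / f"{nid}.json").write_text(
            json.dumps(payload, sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )

    if session.psychometrics is not None:
        pl = ["ecc_deg,dir_deg,contrast,endpoint_x,endpoint_y,responded"]
        for p in session.psychometrics:
            ex, ey = (p.saccade_endpoint if p.saccade_endpoint is not None else (None, None))
            pl.append(
                ",".join(
                    [
                        _fmt(p.target_position[0]),
                        _fmt(p.target_position[1]),
                        _fmt(p.michelson_contrast),
                        _fmt(ex),
                        _fmt(ey),
                        "true" if p.responded_within_1s else "false",
                    ]
                )
            )
        (path / "psychometrics.csv").write_text("\n".join(pl) + "\n", encoding="utf-8")

    md = session.metadata
    meta = {
        "subject": md.subject,
        "date": md.date,
        "field": md.field,
        "inactivation": bool(md.inactivation),
        "extra": md.extra,
    }
    (path / "metadata.json").write_text(
        json.dumps(meta, sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )


def _read_float_column(path: Path, column: str) -> np.ndarray:
    df = pd.read_csv(path)
    if column not in df.columns:
        raise MalformedBundleError(f"malformed bundle: {path.name} lacks column {column!r}")
    return df[column].to_numpy(dtype=float)


def read_session(path: str | Path) -> Session:
    """Read a session bundle; raises on any malformed or invalid content."""
    path = Path(path)
    for required in ("trials.csv", "licks.csv", "metadata.json"):
        if not (path / required).exists():
            raise MalformedBundleError(f"malformed bundle: missing {required}")
    for required_dir in ("spikes", "waveforms"):
        if not (path / required_dir).is_dir():
            raise MalformedBundleError(f"malformed bundle: missing {required_dir}/ directory")

    df = pd.read_csv(path / "trials.csv")
    trials = []
    for row in df.itertuples(index=False):
        cond = str(row.condition)
        if cond not in CONDITIONS:
            raise InvalidTrialTableError(
                f"invalid trial table: unknown condition {cond!r} in trial {row.trial_id}"
            )
        rw = None if pd.isna(row.reward_time) else float(row.reward_time)
        valid = row.valid if isinstance(row.valid, (bool, np.bool_)) else str(row.valid).lower() == "true"
        trials.append(
            Trial(
                trial_id=int(row.trial_id),
                condition=cond,
                field=str(row.field),
                epoch=str(row.epoch),
                fp_onset=float(row.fp_onset),
                cs_onset=float(row.cs_onset),
                cs_offset=float(row.cs_offset),
                reward_time=rw,
                reward_volume=float(row.reward_volume),
                cs_position=(float(row.ecc_deg), float(row.dir_deg)),
                valid=bool(valid),
            )
        )

    licks = LickRecord(_read_float_column(path / "licks.csv", "lick_time"))

    spikes: dict[str, SpikeTrain] = {}
    for f in sorted((path / "spikes").glob("*.csv")):
        nid = f.stem
        times = _read_float_column(f, "spike_time")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise InvalidSpikeTrainError(
                f"invalid spike train: {nid} times not strictly increasing"
            )
        spikes[nid] = SpikeTrain(neuron_id=nid, spike_times=times)

    waveforms: dict[str, list[WaveformTemplate]] = {}
    for f in sorted((path / "waveforms").glob("*.json")):
        payload = json.loads(f.read_text(encoding="utf-8"))
        waveforms[f.stem] = [
            WaveformTemplate(
                samples=np.asarray(e["samples"], dtype=float),
                sample_interval_ms=float(payload["sample_interval_ms"]),
                epoch_label=str(e["label"]),
            )
            for e in payload["epochs"]
        ]

    psychometrics = None
    if (path / "psychometrics.csv").exists():
        pdf = pd.read_csv(path / "psychometrics.csv")
        ptrials = []
        for row in pdf.itertuples(index=False):
            if pd.isna(row.endpoint_x) or pd.isna(row.endpoint_y):
                endpoint = None
            else:
                endpoint = (float(row.endpoint_x), float(row.endpoint_y))
            responded = row.responded if isinstance(row.responded, (bool, np.bool_)) else str(row.responded).lower() == "true"
            ptrials.append(
                PsychometricTrial(
                    target_position=(float(row.ecc_deg), float(row.dir_deg)),
                    michelson_contrast=float(row.contrast),
                    saccade_endpoint=endpoint,
                    responded_within_1s=bool(responded),
                )
            )
        psychometrics = PsychometricRecord(ptrials)

    meta = json.loads((path / "metadata.json").read_text(encoding="utf-8"))
    metadata = SessionMetadata(
        subject=meta.get("subject", "unknown"),
        date=meta.get("date", ""),
        field=meta.get("field", "intact"),
        inactivation=bool(meta.get("inactivation", False)),
        extra=meta.get("extra", {}),
    )

    session = Session(
        trials=TrialTable(trials),
        spikes=spikes,
        waveforms=waveforms,
        licks=licks,
        psychometrics=psychometrics,
        metadata=metadata,
    )
    violations = validate_session(session)
    if violations:
        raise SessionValidationError(violations)
    return session
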