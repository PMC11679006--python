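"""Domain types and label bookkeeping for plantar-pressure FOG trials.

A trial is a pair of per-foot 100 Hz signal tracks (total ground-reaction
force plus the center-of-pressure, COP, in a foot-fixed frame) together with
an annotation track of freezing-of-gait (FOG), turning and standing
intervals.  From the annotations each sample receives one of three gait-state
labels: NONFOG, PREFOG (the 2 s immediately preceding a FOG onset) or FOG.

Conventions
-----------
* Time is seconds from trial start; sample ``i`` sits at ``i / fs`` (0-based).
* Intervals are half-open ``[start, end)`` for sample membership, except that
  a FOG interval also owns the sample falling exactly on its end time.
* COP axes: ``x`` is mediolateral (ML, positive lateral), ``y`` is
  anteroposterior (AP, positive anterior), both in millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np

__all__ = [
    "GaitLabel",
    "EventKind",
    "EventInterval",
    "FootTrack",
    "GridTrack",
    "TrialRecord",
    "ParticipantRecord",
    "Dataset",
    "TrialFormatError",
    "derive_sample_labels",
    "resample_labels",
    "filter_dataset",
    "cohort_summary",
    "validate_events",
]

_EPS = 1e-9


class TrialFormatError(ValueError):
    """Raised when a trial file or record violates the documented format."""


class GaitLabel(IntEnum):
    NONFOG = 0
    PREFOG = 1
    FOG = 2


class EventKind(str, Enum):
    FOG = "FOG"
    TURN = "TURN"
    STAND = "STAND"


@dataclass(frozen=True, order=True)
class EventInterval:
    """A labelled interval ``[start, end)`` in seconds from trial start."""

    start: float
    end: float
    kind: EventKind = field(compare=False, default=EventKind.FOG)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise TrialFormatError(
                f"event {self.kind}: start < end violated ({self.start} >= {self.end})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


def validate_events(events: list[EventInterval]) -> list[EventInterval]:
    """Sort events and check that same-kind intervals do not overlap."""
    out = sorted(events, key=lambda e: (e.start, e.end))
    by_kind: dict[EventKind, EventInterval] = {}
    for ev in out:
        prev = by_kind.get(ev.kind)
        if prev is not None and ev.start < prev.end - _EPS:
            raise TrialFormatError(
                f"overlapping {ev.kind.value} intervals: "
                f"[{prev.start}, {prev.end}) and [{ev.start}, {ev.end})"
            )
        by_kind[ev.kind] = ev
    return out


def _as_1d(name: str, arr) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 1:
        raise TrialFormatError(f"{name} must be 1-D")
    return a


@dataclass
class FootTrack:
    """Per-foot force and COP traces sampled uniformly at ``fs``."""

    times: np.ndarray
    force: np.ndarray
    cop_x: np.ndarray
    cop_y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.times = _as_1d("times", self.times)
        self.force = _as_1d("force", self.force)
        self.cop_x = _as_1d("cop_x", self.cop_x)
        self.cop_y = _as_1d("cop_y", self.cop_y)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.times)
        for name in ("force", "cop_x", "cop_y", "valid"):
            if len(getattr(self, name)) != n:
                raise TrialFormatError(f"{name}: length {len(getattr(self, name))} != times length {n}")
        if n >= 2:
            steps = np.diff(self.times)
            if steps.min() <= 0 or not np.allclose(steps, steps[0], atol=1e-6):
                raise TrialFormatError("times: non-uniform or non-increasing time step")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class GridTrack:
    """Per-foot pressure frames on a fixed sensel layout (foot frame, mm)."""

    times: np.ndarray
    sensel_x: np.ndarray
    sensel_y: np.ndarray
    pressure: np.ndarray  # (n_frames, n_sensels)

    def __post_init__(self) -> None:
        self.times = _as_1d("times", self.times)
        self.sensel_x = _as_1d("sensel_x", self.sensel_x)
        self.sensel_y = _as_1d("sensel_y", self.sensel_y)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if len(self.sensel_x) != len(self.sensel_y):
            raise TrialFormatError("sensel_x/sensel_y: coordinate lists differ in length")
        if self.pressure.ndim != 2 or self.pressure.shape != (len(self.times), len(self.sensel_x)):
            raise TrialFormatError(
                f"pressure: shape {self.pressure.shape} != "
                f"({len(self.times)}, {len(self.sensel_x)})"
            )
        if np.any(self.pressure < 0):
            raise TrialFormatError("pressure: negative values")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class TrialRecord:
    """One walking trial: two foot tracks, event annotations, derived labels."""

    participant_id: str
    trial_id: str
    fs: float
    left: FootTrack | GridTrack
    right: FootTrack | GridTrack
    events: list[EventInterval]
    sample_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise TrialFormatError("left/right tracks differ in length")
        self.events = validate_events(self.events)
        if self.sample_labels is None:
            self.sample_labels = derive_sample_labels(self.events, self.times)
        self.sample_labels = np.asarray(self.sample_labels, dtype=np.int8)
        if len(self.sample_labels) != len(self.left):
            raise TrialFormatError("sample_labels: length mismatch with signal")

    @property
    def times(self) -> np.ndarray:
        return self.left.times

    @property
    def n_samples(self) -> int:
        return len(self.left)

    @property
    def duration(self) -> float:
        """Trial duration in seconds (n samples at fs)."""
        return self.n_samples / self.fs

    def fog_events(self) -> list[EventInterval]:
        return [e for e in self.events if e.kind is EventKind.FOG]

    def events_of(self, *kinds: EventKind) -> list[EventInterval]:
        return [e for e in self.events if e.kind in kinds]


@dataclass
class ParticipantRecord:
    """A participant with demographics, clinical scores and their trials."""

    id: str
    age: float | None = None
    years_since_diagnosis: float | None = None
    nfogq: float | None = None
    updrs3: float | None = None
    froze: bool = False
    trials: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trials:
            has_fog = any(t.fog_events() for t in self.trials)
            if has_fog != self.froze:
                raise TrialFormatError(
                    f"participant {self.id}: froze={self.froze} inconsistent with trials"
                )


@dataclass
class Dataset:
    name: str
    participants: list[ParticipantRecord]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise TrialFormatError(f"dataset {self.name}: duplicate participant ids")

    def __len__(self) -> int:
        return len(self.participants)

    def freezers(self) -> list[ParticipantRecord]:
        return [p for p in self.participants if p.froze]

    def get(self, pid: str) -> ParticipantRecord:
        for p in self.participants:
            if p.id == pid:
                return p
        raise KeyError(pid)


# ---------------------------------------------------------------------------
# labelling


def derive_sample_labels(
    events: list[EventInterval],
    times: np.ndarray,
    pre_fog: float = 2.0,
) -> np.ndarray:
    """Assign a gait-state label to every sample.

    Samples inside a FOG interval (end-inclusive on the sample grid) are FOG;
    samples within ``pre_fog`` seconds before a FOG onset that are not
    themselves FOG are PREFOG; everything else is NONFOG.  FOG takes
    precedence over PREFOG when episodes are less than ``pre_fog`` apart.
    """
    times = np.asarray(times, dtype=float)
    labels = np.full(len(times), GaitLabel.NONFOG, dtype=np.int8)
    fogs = [e for e in events if e.kind is EventKind.FOG]
    for ev in fogs:
        pre = (times >= ev.start - pre_fog - _EPS) & (times < ev.start - _EPS)
        labels[pre] = GaitLabel.PREFOG
    for ev in fogs:
        labels[(times >= ev.start - _EPS) & (times <= ev.end + _EPS)] = GaitLabel.FOG
    return labels


def resample_labels(
    frame_labels: np.ndarray,
    frame_times: np.ndarray,
    target_times: np.ndarray,
) -> np.ndarray:
    """Transfer categorical labels from one time grid to another.

    Each target sample receives the label of the nearest-in-time source frame
    (ties broken toward the earlier frame) — the natural reading of
    interpolation "to the closest data point" for categorical labels, e.g.
    when moving 30 Hz video annotations onto 100 Hz pressure data.
    """
    frame_labels = np.asarray(frame_labels)
    frame_times = np.asarray(frame_times, dtype=float)
    target_times = np.asarray(target_times, dtype=float)
    if frame_labels.size == 0:
        raise TrialFormatError("resample_labels: empty label track")
    if len(frame_labels) != len(frame_times):
        raise TrialFormatError("resample_labels: labels/times length mismatch")
    idx = np.searchsorted(frame_times, target_times)
    idx = np.clip(idx, 0, len(frame_times) - 1)
    prev = np.clip(idx - 1, 0, len(frame_times) - 1)
    d_next = np.abs(frame_times[idx] - target_times)
    d_prev = np.abs(target_times - frame_times[prev])
    # strictly-closer wins; exact tie goes to the earlier frame
    take_prev = d_prev <= d_next + _EPS
    chosen = np.where(take_prev, prev, idx)
    return frame_labels[chosen]


# ---------------------------------------------------------------------------
# dataset-level operations


def filter_dataset(
    ds: Dataset,
    exclude_ids: list[str] | tuple[str, ...] = (),
    exclude_nonfreezers: bool = False,
    name: str | None = None,
) -> Dataset:
    """Return a new dataset with the given participants removed.

    Mirrors the cohort modifications used to probe outlier effects: dropping
    a named heavy freezer, dropping all non-freezers, or both.
    """
    known = {p.id for p in ds.participants}
    unknown = [pid for pid in exclude_ids if pid not in known]
    if unknown:
        raise KeyError(f"unknown participant id(s): {unknown}")
    kept = [
        p
        for p in ds.participants
        if p.id not in set(exclude_ids) and not (exclude_nonfreezers and not p.froze)
    ]
    return Dataset(name=name or ds.name, participants=kept)


def _mean_sd(values: list[float]) -> tuple[float, float, int]:
    vals = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    n = len(vals)
    if n == 0:
        return (math.nan, math.nan, 0)
    mean = sum(vals) / n
    if n < 2:
        return (mean, math.nan, n)
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    return (mean, sd, n)


def cohort_summary(
    ds: Dataset,
    target_zone_durations: dict[str, float] | None = None,
):
    """Per-participant testing summary with a mean/SD (sample SD, n-1) row.

    Columns: trial count, total trial duration, FOG episode count, total FOG
    duration and — when supplied — total MTD-target-zone duration.  Fields
    missing for some participants (zone durations for non-freezers, absent
    clinical scores) are excluded from that column's mean, SD and n.
    Returns a pandas DataFrame indexed by participant id plus ``mean``/``sd``
    rows.
    """
    import pandas as pd

    if not ds.participants:
        raise ValueError("cohort_summary: empty dataset")
    rows = {}
    for p in ds.participants:
        zone = None
        if target_zone_durations is not None:
            zone = target_zone_durations.get(p.id)
        rows[p.id] = {
            "age": p.age,
            "years_since_diagnosis": p.years_since_diagnosis,
            "nfogq": p.nfogq,
            "updrs3": p.updrs3,
            "n_trials": len(p.trials) if p.trials else None,
            "total_trial_duration_s": sum(t.duration for t in p.trials) if p.trials else None,
            "n_fog": sum(len(t.fog_events()) for t in p.trials) if p.trials else None,
            "total_fog_duration_s": (
                sum(e.duration for t in p.trials for e in t.fog_events()) if p.trials else None
            ),
            "total_target_zone_s": zone,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    stats = {col: _mean_sd(list(df[col])) for col in df.columns}
    df.loc["mean"] = {c: s[0] for c, s in stats.items()}
    df.loc["sd"] = {c: s[1] for c, s in stats.items()}
    df.loc["n"] = {c: s[2] for c, s in stats.items()}
    return df


def summarize_table(df, ddof: int = 1):
    """Append mean/sd/n rows (NaN-skipping, sample SD) to a numeric frame."""
    out = df.copy()
    out.loc["mean"] = df.mean(skipna=True)
    out.loc["sd"] = df.std(skipna=True, ddof=ddof)
    out.loc["n"] = df.notna().sum()
    return out
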