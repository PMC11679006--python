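"""Reading and writing trial files and cohort manifests.

A trial is stored as one wide CSV plus a JSON annotation sidecar of the same
stem.  Two CSV layouts exist:

* signal form — ``time,l_force,l_cop_x,l_cop_y,l_valid,r_force,r_cop_x,
  r_cop_y,r_valid``;
* grid form — ``time,l_p_0..l_p_{k},r_p_0..r_p_{k}`` with the per-foot sensel
  coordinates carried in the sidecar under ``sensels``.

The sidecar holds ``{participant_id, trial_id, fs, events:[{kind,start,end}]}``.
A cohort manifest JSON lists participants (demographics, clinical scores,
froze flag) with relative paths to their trial CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Dataset,
    EventInterval,
    EventKind,
    FootTrack,
    GridTrack,
    ParticipantRecord,
    TrialFormatError,
    TrialRecord,
)

__all__ = ["read_trial", "write_trial", "read_manifest", "write_dataset"]

_SIGNAL_COLS = [
    "time",
    "l_force", "l_cop_x", "l_cop_y", "l_valid",
    "r_force", "r_cop_x", "r_cop_y", "r_valid",
]

_FLOAT_FMT = "%.10g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trial(trial: TrialRecord, path: str | Path) -> None:
    """Write a trial CSV and its JSON sidecar; read_trial round-trips it."""
    path = Path(path)
    sidecar: dict = {
        "participant_id": trial.participant_id,
        "trial_id": trial.trial_id,
        "fs": trial.fs,
        "events": [
            {"kind": e.kind.value, "start": e.start, "end": e.end} for e in trial.events
        ],
    }
    if isinstance(trial.left, GridTrack):
        cols = {"time": trial.left.times}
        for prefix, track in (("l", trial.left), ("r", trial.right)):
            for k in range(track.pressure.shape[1]):
                cols[f"{prefix}_p_{k}"] = track.pressure[:, k]
        sidecar["sensels"] = {
            side: {"x": list(track.sensel_x), "y": list(track.sensel_y)}
            for side, track in (("left", trial.left), ("right", trial.right))
        }
        df = pd.DataFrame(cols)
    else:
        df = pd.DataFrame(
            {
                "time": trial.left.times,
                "l_force": trial.left.force,
                "l_cop_x": trial.left.cop_x,
                "l_cop_y": trial.left.cop_y,
                "l_valid": trial.left.valid.astype(int),
                "r_force": trial.right.force,
                "r_cop_x": trial.right.cop_x,
                "r_cop_y": trial.right.cop_y,
                "r_valid": trial.right.valid.astype(int),
            }
        )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def _parse_events(raw: list[dict]) -> list[EventInterval]:
    events = []
    for item in raw:
        try:
            kind = EventKind(item["kind"])
        except ValueError as exc:
            raise TrialFormatError(f"events: unknown kind {item['kind']!r}") from exc
        events.append(EventInterval(start=float(item["start"]), end=float(item["end"]), kind=kind))
    return events


def read_trial(path: str | Path) -> TrialRecord:
    """Read a trial CSV + JSON sidecar into a fully populated TrialRecord."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not path.exists():
        raise TrialFormatError(f"missing trial CSV: {path}")
    if not sidecar_path.exists():
        raise TrialFormatError(f"missing annotation sidecar: {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for key in ("participant_id", "trial_id", "fs", "events"):
        if key not in meta:
            raise TrialFormatError(f"sidecar: missing field {key!r}")
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise TrialFormatError("trial CSV: missing column 'time'")
    times = df["time"].to_numpy(dtype=float)
    events = _parse_events(meta["events"])

    if "sensels" in meta:
        tracks = {}
        for side, prefix in (("left", "l"), ("right", "r")):
            coords = meta["sensels"][side]
            pcols = sorted(
                (c for c in df.columns if c.startswith(f"{prefix}_p_")),
                key=lambda c: int(c.rsplit("_", 1)[1]),
            )
            if len(pcols) != len(coords["x"]):
                raise TrialFormatError(f"{side}: pressure columns != sensel coordinates")
            tracks[side] = GridTrack(
                times=times,
                sensel_x=np.asarray(coords["x"], dtype=float),
                sensel_y=np.asarray(coords["y"], dtype=float),
                pressure=df[pcols].to_numpy(dtype=float),
            )
        left, right = tracks["left"], tracks["right"]
    else:
        missing = [c for c in _SIGNAL_COLS if c not in df.columns]
        if missing:
            raise TrialFormatError(f"trial CSV: missing column(s) {missing}")
        left = FootTrack(
            times=times,
            force=df["l_force"].to_numpy(float),
            cop_x=df["l_cop_x"].to_numpy(float),
            cop_y=df["l_cop_y"].to_numpy(float),
            valid=df["l_valid"].to_numpy(bool),
        )
        right = FootTrack(
            times=times,
            force=df["r_force"].to_numpy(float),
            cop_x=df["r_cop_x"].to_numpy(float),
            cop_y=df["r_cop_y"].to_numpy(float),
            valid=df["r_valid"].to_numpy(bool),
        )

    return TrialRecord(
        participant_id=str(meta["participant_id"]),
        trial_id=str(meta["trial_id"]),
        fs=float(meta["fs"]),
        left=left,
        right=right,
        events=events,
    )


def write_dataset(ds: Dataset, out_dir: str | Path) -> Path:
    """Write every trial plus a cohort manifest JSON; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"name": ds.name, "participants": []}
    for p in ds.participants:
        pdir = out_dir / p.id
        pdir.mkdir(exist_ok=True)
        paths = []
        for trial in p.trials:
            rel = Path(p.id) / f"{trial.trial_id}.csv"
            write_trial(trial, out_dir / rel)
            paths.append(str(rel))
        manifest["participants"].append(
            {
                "id": p.id,
                "age": p.age,
                "years_since_diagnosis": p.years_since_diagnosis,
                "nfogq": p.nfogq,
                "updrs3": p.updrs3,
                "froze": p.froze,
                "trials": paths,
            }
        )
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path


def read_manifest(manifest_path: str | Path) -> Dataset:
    """Load a cohort manifest JSON and all trials it references."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    participants = []
    for entry in manifest["participants"]:
        trials = [read_trial(base / rel) for rel in entry["trials"]]
        participants.append(
            ParticipantRecord(
                id=entry["id"],
                age=entry.get("age"),
                years_since_diagnosis=entry.get("years_since_diagnosis"),
                nfogq=entry.get("nfogq"),
                updrs3=entry.get("updrs3"),
                froze=bool(entry.get("froze")),
                trials=trials,
            )
        )
    return Dataset(name=manifest.get("name", manifest_path.stem), participants=participants)
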