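"""Pipeline configuration.

The pipeline has ~15 numeric constants (window geometry, pre-FOG horizon,
validity threshold, MTD rules, ensemble hyper-parameters, ...).  They live
in one structured, hashable config so every output can record exactly which
values produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the FOG prediction pipeline, with study defaults.

    Durations are seconds, the validity threshold is a force fraction, the
    reversal hysteresis is millimetres.
    """

    # windowing / labelling
    window: float = 1.0          # analysis window length
    shift: float = 0.2           # shift between consecutive windows (0.8 s overlap)
    prefog: float = 2.0          # pre-FOG horizon before each onset
    validity_threshold: float = 0.05  # min fraction of two-foot force for valid COP

    # MTD / episode evaluation
    mtd_run_length: int = 3      # consecutive target windows that trigger an MTD
    target_zone: float = 6.0     # initial prediction-zone length before onset
    post_event_delay: float = 1.0  # zone start delay after turn/stand events
    no_cue: float = 2.5          # refractory period between kept MTDs
    gait_init: float = 1.0       # first second of walking after standing

    # ensemble
    n_learners: int = 100
    max_splits: int = 5
    learn_rate: float = 0.1
    sampling_ratio: float = 1.0  # majority:minority examples per boosting round
    score_threshold: float = 0.5

    # features
    wavelet: str = "db4"
    wavelet_level: int = 4
    reversal_hysteresis: float = 1.0

    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls().to_dict())
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
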