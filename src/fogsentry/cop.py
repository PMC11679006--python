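"""Center-of-pressure kinematics.

Per-foot COP traces come either directly from the recording or as the
pressure-weighted centroid of a sensel grid.  A per-sample validity rule
discards COP readings while a foot is in swing: the foot must carry more
than 5% of the two-foot total ground-reaction force.  Invalid spans are
bridged by linear interpolation (held at the edges) before differentiation,
and the validity mask is carried forward so downstream features can ignore
repaired samples.  COP velocity is the first time derivative, computed with
central differences (one-sided at the ends) — exact for linear signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FootTrack, GridTrack, TrialFormatError

__all__ = [
    "CopSeries",
    "compute_cop",
    "validity_mask",
    "fill_invalid",
    "cop_velocity",
    "foot_cop_series",
    "trial_cop_series",
]


@dataclass
class CopSeries:
    """Filled COP position and velocity with the original validity mask."""

    times: np.ndarray
    cop_x: np.ndarray
    cop_y: np.ndarray
    vel_x: np.ndarray
    vel_y: np.ndarray
    valid: np.ndarray


def compute_cop(
    pressure: np.ndarray, sensel_x: np.ndarray, sensel_y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pressure-weighted centroid of the sensel grid, per frame.

    Accepts one frame ``(n_sensels,)`` or a stack ``(n_frames, n_sensels)``.
    Returns ``(cop_x, cop_y, defined)`` where all-zero frames yield NaN COP
    and ``defined`` False.
    """
    p = np.atleast_2d(np.asarray(pressure, dtype=float))
    if np.any(p < 0):
        raise ValueError("compute_cop: negative pressures")
    total = p.sum(axis=1)
    defined = total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cx = p @ np.asarray(sensel_x, float) / total
        cy = p @ np.asarray(sensel_y, float) / total
    cx[~defined] = np.nan
    cy[~defined] = np.nan
    if np.ndim(pressure) == 1:
        return cx[0], cy[0], defined[0]
    return cx, cy, defined


def validity_mask(
    left_force: np.ndarray, right_force: np.ndarray, threshold: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Per-foot COP validity: strict >5% share of the two-foot total force.

    Scale invariant; samples where both feet read zero are invalid for both.
    """
    lf = np.asarray(left_force, dtype=float)
    rf = np.asarray(right_force, dtype=float)
    if np.any(lf < 0) or np.any(rf < 0):
        raise ValueError("validity_mask: negative forces")
    total = lf + rf
    return lf > threshold * total, rf > threshold * total


def fill_invalid(series: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Bridge invalid samples: linear interpolation inside, hold at the ends.

    Raises on an all-invalid series; the mask itself is untouched.
    """
    series = np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise TrialFormatError("fill_invalid: no valid samples in series")
    if mask.all():
        return series.copy()
    idx = np.arange(len(series))
    # np.interp holds end values flat outside the valid support
    return np.interp(idx, idx[mask], series[mask])


def cop_velocity(series: np.ndarray, fs: float) -> np.ndarray:
    """First derivative: central differences interior, one-sided at the ends."""
    series = np.asarray(series, dtype=float)
    if len(series) < 3:
        raise ValueError("cop_velocity: need at least 3 samples")
    return np.gradient(series, 1.0 / fs)


def foot_cop_series(
    times: np.ndarray,
    cop_x: np.ndarray,
    cop_y: np.ndarray,
    valid: np.ndarray,
    fs: float,
) -> CopSeries:
    """Fill invalid COP spans and differentiate, keeping the mask."""
    fx = fill_invalid(cop_x, valid)
    fy = fill_invalid(cop_y, valid)
    return CopSeries(
        times=np.asarray(times, float),
        cop_x=fx,
        cop_y=fy,
        vel_x=cop_velocity(fx, fs),
        vel_y=cop_velocity(fy, fs),
        valid=np.asarray(valid, bool),
    )


def _grid_to_foot(track: GridTrack) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cx, cy, defined = compute_cop(track.pressure, track.sensel_x, track.sensel_y)
    force = track.pressure.sum(axis=1)
    return force, np.where(defined, cx, 0.0), np.where(defined, cy, 0.0)


def trial_cop_series(trial, threshold: float = 0.05) -> tuple[CopSeries, CopSeries]:
    """Per-foot CopSeries for a trial, applying the force-share validity rule.

    Grid tracks are first reduced to force + centroid COP; signal tracks are
    used as-is.  Validity is recomputed from the forces so the same rule
    applies to both input forms.
    """
    sides = []
    forces = []
    cops = []
    for track in (trial.left, trial.right):
        if isinstance(track, GridTrack):
            force, cx, cy = _grid_to_foot(track)
        elif isinstance(track, FootTrack):
            force, cx, cy = track.force, track.cop_x, track.cop_y
        else:  # pragma: no cover
            raise TypeError(f"unsupported track type {type(track)!r}")
        forces.append(np.asarray(force, float))
        cops.append((cx, cy))
    lv, rv = validity_mask(forces[0], forces[1], threshold)
    for (cx, cy), valid in zip(cops, (lv, rv)):
        sides.append(foot_cop_series(trial.times, cx, cy, valid, trial.fs))
    return sides[0], sides[1]
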