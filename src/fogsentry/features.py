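"""Sliding-window segmentation and the 8 COP features.

Trials are sliced into 1 s windows shifted by 0.2 s (0.8 s overlap), aligned
to the trial start.  A window belongs to the target class iff every sample
in it is PREFOG or FOG; any NONFOG sample makes it non-target.

Four features per foot, eight in total, in this fixed order:

====  =========  =====================================================
 #    name       description
====  =========  =====================================================
 1    revAP_L    number of AP COP reversals, left
 2    revAP_R    number of AP COP reversals, right
 3    domML_L    dominant frequency of ML COP velocity, left (Hz)
 4    domML_R    dominant frequency of ML COP velocity, right (Hz)
 5    domAP_L    dominant frequency of AP COP velocity, left (Hz)
 6    domAP_R    dominant frequency of AP COP velocity, right (Hz)
 7    wavAP_L    mean wavelet approximation-coefficient power of AP
                 COP position, left (mm^2)
 8    wavAP_R    same, right
====  =========  =====================================================

Reversals are counted on valid samples only with a small hysteresis;
spectral features use the gap-filled traces.  A foot with no valid sample
in a window contributes zeros for its four features and flags the window
degenerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .config import RunConfig
from .cop import trial_cop_series
from .core import GaitLabel, TrialRecord

__all__ = [
    "Window",
    "FeatureVector",
    "FEATURE_NAMES",
    "make_windows",
    "classify_window",
    "count_ap_reversals",
    "dominant_frequency",
    "wavelet_approx_power",
    "extract_features",
    "feature_matrix",
]

FEATURE_NAMES = [
    "revAP_L", "revAP_R",
    "domML_L", "domML_R",
    "domAP_L", "domAP_R",
    "wavAP_L", "wavAP_R",
]


@dataclass(frozen=True)
class Window:
    """One analysis window: ``[start, end)`` seconds, samples ``[i0, i1)``."""

    index: int
    start: float
    end: float
    i0: int
    i1: int


@dataclass(frozen=True)
class FeatureVector:
    revAP_L: float
    revAP_R: float
    domML_L: float
    domML_R: float
    domAP_L: float
    domAP_R: float
    wavAP_L: float
    wavAP_R: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def make_windows(
    n_samples: int, fs: float, win: float = 1.0, shift: float = 0.2
) -> list[Window]:
    """Windows of length ``win`` stepped by ``shift``, fully inside the trial.

    Count is exactly ``floor((T - win)/shift) + 1`` for trial duration
    ``T = n_samples / fs``.
    """
    win_n = int(round(win * fs))
    shift_n = int(round(shift * fs))
    if n_samples < win_n:
        raise ValueError(
            f"trial of {n_samples / fs:.2f} s is shorter than one {win} s window"
        )
    count = (n_samples - win_n) // shift_n + 1
    return [
        Window(
            index=k,
            start=k * shift_n / fs,
            end=(k * shift_n + win_n) / fs,
            i0=k * shift_n,
            i1=k * shift_n + win_n,
        )
        for k in range(count)
    ]


def classify_window(labels: np.ndarray) -> bool:
    """True (target) iff every sample label in the window is PREFOG or FOG."""
    labels = np.asarray(labels)
    return bool(np.all(labels != GaitLabel.NONFOG))


def count_ap_reversals(
    segment: np.ndarray,
    valid: np.ndarray | None = None,
    hysteresis: float = 1.0,
) -> int:
    """Direction changes of the AP COP trajectory within one window.

    Alternating local extrema are accepted when the excursion from the
    previously accepted extremum exceeds ``hysteresis`` (mm), which
    suppresses sensor noise.  Only valid samples are considered and the
    detector resets across invalid runs; an all-invalid window counts 0.
    """
    x = np.asarray(segment, dtype=float)
    if valid is None:
        valid = np.ones(len(x), dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    total = 0
    i = 0
    n = len(x)
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        total += _count_reversals_run(x[i:j], hysteresis)
        i = j
    return total


def _count_reversals_run(x: np.ndarray, delta: float) -> int:
    if len(x) < 2:
        return 0
    count = 0
    direction = 0  # 0 = not yet established
    ext = x[0]
    for v in x[1:]:
        if direction == 0:
            if v - ext > delta:
                direction = 1
                ext = v
            elif ext - v > delta:
                direction = -1
                ext = v
        elif direction == 1:
            if v > ext:
                ext = v
            elif ext - v > delta:
                count += 1
                direction = -1
                ext = v
        else:
            if v < ext:
                ext = v
            elif v - ext > delta:
                count += 1
                direction = 1
                ext = v
    return count


def dominant_frequency(segment: np.ndarray, fs: float = 100.0) -> float:
    """Frequency of the maximum-magnitude FFT bin, DC excluded.

    The segment is mean-removed and transformed without zero padding, so a
    1 s segment at 100 Hz gives 1 Hz resolution.  Ties (including the
    degenerate all-zero spectrum) resolve to the lowest frequency.
    """
    return float(_dominant_frequency_batch(np.asarray(segment, float)[None, :], fs)[0])


def _dominant_frequency_batch(segments: np.ndarray, fs: float) -> np.ndarray:
    x = segments - segments.mean(axis=1, keepdims=True)
    mag = np.abs(np.fft.rfft(x, axis=1))
    freqs = np.fft.rfftfreq(segments.shape[1], d=1.0 / fs)
    # round tiny magnitudes to zero so numerically flat spectra tie to bin 1
    mag = np.where(mag < 1e-12, 0.0, mag)
    best = np.argmax(mag[:, 1:], axis=1) + 1  # argmax returns first = lowest
    return freqs[best]


def wavelet_approx_power(
    segment: np.ndarray,
    wavelet: str = "db4",
    level: int = 4,
    demean: bool = True,
) -> float:
    """Mean squared approximation coefficient of a multi-level DWT.

    Daubechies-4 at level 4 with symmetric padding keeps roughly the 0–3 Hz
    locomotor band of a 100 Hz signal.  The segment is mean-removed by
    default so the feature, like the others, ignores a constant COP offset.
    """
    return float(
        _wavelet_power_batch(np.asarray(segment, float)[None, :], wavelet, level, demean)[0]
    )


def _wavelet_power_batch(
    segments: np.ndarray, wavelet: str, level: int, demean: bool
) -> np.ndarray:
    x = segments
    if demean:
        x = x - x.mean(axis=1, keepdims=True)
    with warnings.catch_warnings():
        # level 4 on a 1 s segment trades boundary effects for the 0-3 Hz
        # locomotor approximation band; the trade-off is deliberate
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, mode="symmetric", level=level, axis=1)
    approx = coeffs[0]
    return np.mean(approx**2, axis=1)


def _window_view(arr: np.ndarray, win_n: int, shift_n: int, count: int) -> np.ndarray:
    view = np.lib.stride_tricks.sliding_window_view(arr, win_n)[::shift_n]
    return view[:count]


def feature_matrix(
    trial: TrialRecord, cfg: RunConfig | None = None
) -> tuple[list[Window], np.ndarray, np.ndarray, np.ndarray]:
    """All windows of a trial with their features and true classes.

    Returns ``(windows, X, y, degenerate)`` where ``X`` is
    ``(n_windows, 8)`` in FEATURE_NAMES order, ``y`` is the boolean target
    class from the ground-truth labels, and ``degenerate`` marks windows
    where at least one foot had no valid sample.
    """
    cfg = cfg or RunConfig()
    fs = trial.fs
    windows = make_windows(trial.n_samples, fs, cfg.window, cfg.shift)
    count = len(windows)
    win_n = windows[0].i1 - windows[0].i0
    shift_n = windows[1].i0 - windows[0].i0 if count > 1 else win_n

    left, right = trial_cop_series(trial, cfg.validity_threshold)
    X = np.zeros((count, 8), dtype=float)
    degenerate = np.zeros(count, dtype=bool)

    for f, series in ((0, left), (1, right)):
        valid_w = _window_view(series.valid.astype(np.uint8), win_n, shift_n, count)
        any_valid = valid_w.any(axis=1)
        degenerate |= ~any_valid

        dom_ml = _dominant_frequency_batch(
            _window_view(series.vel_x, win_n, shift_n, count), fs
        )
        dom_ap = _dominant_frequency_batch(
            _window_view(series.vel_y, win_n, shift_n, count), fs
        )
        wav_ap = _wavelet_power_batch(
            _window_view(series.cop_y, win_n, shift_n, count),
            cfg.wavelet,
            cfg.wavelet_level,
            demean=True,
        )
        cop_y_w = _window_view(series.cop_y, win_n, shift_n, count)
        rev = np.array(
            [
                count_ap_reversals(cop_y_w[k], valid_w[k].astype(bool), cfg.reversal_hysteresis)
                for k in range(count)
            ],
            dtype=float,
        )
        X[:, 0 + f] = np.where(any_valid, rev, 0.0)
        X[:, 2 + f] = np.where(any_valid, dom_ml, 0.0)
        X[:, 4 + f] = np.where(any_valid, dom_ap, 0.0)
        X[:, 6 + f] = np.where(any_valid, wav_ap, 0.0)

    labels_w = _window_view(trial.sample_labels, win_n, shift_n, count)
    y = np.all(labels_w != GaitLabel.NONFOG, axis=1)
    return windows, X, y, degenerate


def extract_features(
    trial: TrialRecord, window: Window, cfg: RunConfig | None = None
) -> FeatureVector:
    """The 8-feature vector for a single window of a trial."""
    _, X, _, degenerate = feature_matrix(trial, cfg)
    row = X[window.index]
    return FeatureVector(*row, degenerate=bool(degenerate[window.index]))
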