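"""Independent convolution-based DWT oracle for the wavelet-power feature.

Implements the cascade of low-pass filter + downsample steps directly with
numpy convolution and half-sample symmetric boundary extension, using the
published Daubechies-4 decomposition filter taps.  Kept free of PyWavelets
so it can serve as an independent cross-check.
"""

import numpy as np

# Daubechies-4 decomposition low-pass filter (standard published taps)
_DB4_DEC_LO = np.array(
    [
        -0.010597401784997278,
        0.032883011666982945,
        0.030841381835986965,
        -0.18703481171888114,
        -0.02798376941698385,
        0.6308807679295904,
        0.7148465705525415,
        0.23037781330885523,
    ]
)

_FILTERS = {"db4": _DB4_DEC_LO}


def _dwt_approx_step(x: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """One analysis step: symmetric-extend, convolve with lo, downsample by 2."""
    L = len(lo)
    ext = np.concatenate([x[: L - 1][::-1], x, x[-(L - 1):][::-1]])
    full = np.convolve(ext, lo, mode="valid")
    return full[1::2]


def wavedec_approx_oracle(x: np.ndarray, wavelet: str, level: int) -> np.ndarray:
    """Level-``level`` approximation coefficients of the multilevel DWT."""
    a = np.asarray(x, dtype=float)
    lo = _FILTERS[wavelet]
    for _ in range(level):
        a = _dwt_approx_step(a, lo)
    return a
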