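"""sRGB transfer functions on bare float arrays.

The IEC 61966-2-1 piecewise curve. Kept private so the image-level
operations in :mod:`lfaquant.photometric` stay the public surface.
"""

from __future__ import annotations

import numpy as np

_A = 0.055
_PHI = 12.92
_CUT_LIN = 0.0031308
_CUT_ENC = 0.04045


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    """Linear light -> sRGB-encoded values, elementwise, both in [0, 1]."""
    x = np.asarray(linear, dtype=float)
    return np.where(x <= _CUT_LIN, _PHI * x, (1 + _A) * np.power(np.maximum(x, 0.0), 1 / 2.4) - _A)


def srgb_decode(encoded: np.ndarray) -> np.ndarray:
    """sRGB-encoded values -> linear light, elementwise, both in [0, 1]."""
    x = np.asarray(encoded, dtype=float)
    return np.where(x <= _CUT_ENC, x / _PHI, np.power((np.maximum(x, 0.0) + _A) / (1 + _A), 2.4))


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Rec. 709 luminance of a (..., 3) linear RGB array."""
    rgb = np.asarray(rgb, dtype=float)
    return rgb @ np.array([0.2126, 0.7152, 0.0722])
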