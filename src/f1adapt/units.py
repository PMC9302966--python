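"""Frequency-scale conversions.

All analyses operate in mels, the perceptual frequency scale; the
O'Shaughnessy form m = 2595 * log10(1 + f/700) is used, matching the
convention of the real-time formant-perturbation software ecosystem.
The constant pair is exposed for configuration.
"""

from __future__ import annotations

import numpy as np

MEL_SCALE = 2595.0
MEL_BREAK_HZ = 700.0

__all__ = ["hz_to_mel", "mel_to_hz", "MEL_SCALE", "MEL_BREAK_HZ"]


def hz_to_mel(f_hz, scale: float = MEL_SCALE, break_hz: float = MEL_BREAK_HZ):
    """Convert frequency in Hz to mels.  Strictly increasing on [0, inf)."""
    f = np.asarray(f_hz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    out = scale * np.log10(1.0 + f / break_hz)
    return float(out) if np.isscalar(f_hz) else out


def mel_to_hz(m, scale: float = MEL_SCALE, break_hz: float = MEL_BREAK_HZ):
    """Inverse of :func:`hz_to_mel`."""
    mm = np.asarray(m, dtype=float)
    if np.any(mm < 0):
        raise ValueError("mel value must be >= 0")
    out = break_hz * (10.0 ** (mm / scale) - 1.0)
    return float(out) if np.isscalar(m) else out
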