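"""Minimal preprocessing: a power-line notch filter, nothing else.

The staging pipeline deliberately applies no detrending and no artifact
rejection; the scattering features absorb slow drifts and transients.  Only
mains interference is removed, with a narrow zero-phase IIR notch whose
default quality factor (30) leaves the 35–80 Hz analysis band essentially
untouched outside ±3 Hz of the line frequency.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import filtfilt, iirnotch

from .io import Recording

DEFAULT_NOTCH_HZ = 60.0
DEFAULT_Q = 30.0


def notch_filter(
    signal: np.ndarray,
    fs: float,
    f0: float = DEFAULT_NOTCH_HZ,
    quality: float = DEFAULT_Q,
) -> np.ndarray:
    """Zero-phase second-order IIR notch at ``f0`` Hz.

    Applied forward-backward (``filtfilt``) so the phase response is zero
    and the attenuation in dB doubles relative to a single pass.  Length is
    preserved.
    """
    x = np.asarray(signal, dtype=float)
    if not 0 < f0 < fs / 2:
        raise ValueError(f"notch frequency {f0} Hz must lie in (0, {fs / 2}) Hz")
    b, a = iirnotch(f0, quality, fs=fs)
    return filtfilt(b, a, x)


def notch_recording(
    recording: Recording,
    f0: float = DEFAULT_NOTCH_HZ,
    quality: float = DEFAULT_Q,
) -> Recording:
    """Notch-filter every channel of a recording (EEG and EMG alike)."""
    return Recording(
        subject_id=recording.subject_id,
        fs=recording.fs,
        channels={
            name: notch_filter(x, recording.fs, f0, quality)
            for name, x in recording.channels.items()
        },
        start_time=recording.start_time,
    )
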