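"""WAV input/output and amplitude/level conventions.

All in-memory audio is float64/float32 in linear pressure units where a
sample amplitude of 1.0 corresponds to ``FULLSCALE_DB`` dB re 1 uPa.  Levels
are therefore ``20*log10(rms) + FULLSCALE_DB`` dB re 1 uPa.  The constant is
a pure bookkeeping convention: every synthesis and measurement routine takes
an optional ``ref_db`` so a different acquisition-chain calibration can be
applied.
"""

from __future__ import annotations

import wave as _wave
from pathlib import Path

import numpy as np
from scipy.io import wavfile as _wavfile

#: dB re 1 uPa represented by digital amplitude 1.0 (default calibration).
FULLSCALE_DB = 140.0


def rms(x: np.ndarray) -> float:
    """Root mean square of a signal."""
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean(x * x)))


def db(x: float, floor: float = 1e-300) -> float:
    """20*log10(|x|), guarded against zero."""
    return float(20.0 * np.log10(max(abs(float(x)), floor)))


def spl_db(x: np.ndarray, ref_db: float = FULLSCALE_DB) -> float:
    """RMS sound pressure level of ``x`` in dB re 1 uPa."""
    return db(rms(x)) + ref_db


def write_wav(path: str | Path, data: np.ndarray, fs: int, bit_depth: int = 24) -> None:
    """Write a (n_samples, n_channels) float array as integer PCM WAV.

    Parameters
    ----------
    data:
        Float samples in [-1, 1]; values outside are clipped.
    bit_depth:
        16 or 24.
    """
    if bit_depth not in (16, 24):
        raise ValueError(f"bit_depth must be 16 or 24, got {bit_depth}")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < data.shape[1]:  # allow (ch, n) input
        data = data.T
    data = np.clip(data, -1.0, 1.0)
    full = 2 ** (bit_depth - 1) - 1
    ints = np.round(data * full).astype("<i4")
    n_bytes = bit_depth // 8
    raw = ints.reshape(-1, 1).view("<u1")[:, :n_bytes].tobytes()
    with _wave.open(str(path), "wb") as w:
        w.setnchannels(data.shape[1])
        w.setsampwidth(n_bytes)
        w.setframerate(int(fs))
        w.writeframes(raw)


def read_wav(path: str | Path) -> tuple[int, np.ndarray]:
    """Read a WAV file into (fs, float array of shape (n_samples, n_channels)).

    Integer PCM is normalised to [-1, 1); float WAVs pass through.
    """
    fs, data = _wavfile.read(str(path))
    if data.ndim == 1:
        data = data[:, None]
    if np.issubdtype(data.dtype, np.integer):
        # scipy left-justifies 24-bit samples inside int32
        scale = float(2 ** (8 * data.dtype.itemsize - 1))
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    return int(fs), data
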