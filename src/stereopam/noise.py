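"""Octave-band ambient-noise measurement and sea-state calibration.

The calibration chain converts a wind-speed series into wave height
(:func:`wave_height`), wave height into a continuous sea state
(:func:`sea_state`), sea state into a predicted ambient spectrum level via a
fitted deep-water reference model (:func:`wenz_psd` / :func:`wenz_level`),
and finally compares predicted with measured octave levels to recover the
per-session gain of the acquisition chain (:func:`calibrate_gain`).

Only one channel of a stereo recording is normally analysed for noise (the
second channel of the original hardware carries corrupt signal in some
sessions); this is a caller decision, all functions here take mono input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy.interpolate import PchipInterpolator

from .audio import FULLSCALE_DB
from . import stats as _stats

__all__ = [
    "OCTAVE_CENTERS_HZ",
    "OctaveBandLevels",
    "SessionGain",
    "octave_spl",
    "octave_levels",
    "wave_height",
    "sea_state",
    "sea_state_to_wave_height",
    "wenz_psd",
    "wenz_level",
    "calibrate_gain",
    "period_compare",
    "STANDARD_GRAVITY",
]

#: the nine analysed octave-band centres, Hz
OCTAVE_CENTERS_HZ = (50, 100, 200, 400, 800, 1600, 3200, 6400, 12800)

STANDARD_GRAVITY = 9.80665  # m/s^2

# WMO sea-state code vs significant wave height (m): upper boundary of each
# state.  A monotone cubic through these knots gives the continuous scale.
_WMO_HEIGHTS_M = np.array([0.0, 0.1, 0.5, 1.25, 2.5, 4.0, 6.0, 9.0, 14.0, 20.0])
_WMO_STATES = np.arange(10.0)
_H_TO_SS = PchipInterpolator(_WMO_HEIGHTS_M, _WMO_STATES, extrapolate=False)
# dense tabulation of the forward curve; its linear interpolation is the
# (numerically exact) inverse used by sea_state_to_wave_height
_H_DENSE = np.linspace(0.0, _WMO_HEIGHTS_M[-1], 4001)
_SS_DENSE = _H_TO_SS(_H_DENSE)

# Deep-water ambient-noise spectrum model, versioned coefficient set.
# Components (spectrum level, dB re 1 uPa^2/Hz; f in kHz; wind w in m/s):
#   turbulence: t0 + t1*log10(f)
#   shipping:   s0 + s1*(ship - 0.5) + s2*log10(f) + s3*log10(f + s4)
#   wind:       w0 + w1*sqrt(w) + w2*log10(f) + w3*log10(f + w4)
#   thermal:    h0 + h1*log10(f)
WENZ_COEFFS_VERSION = "2024.1"
_WENZ = {
    "turbulence": (17.0, -30.0),
    "shipping": (40.0, 20.0, 26.0, -60.0, 0.03),
    "wind": (50.0, 7.5, 20.0, -40.0, 0.4),
    "thermal": (-15.0, 20.0),
}


@dataclass
class OctaveBandLevels:
    """Nine octave-band SPLs for one recording."""

    centers_hz: tuple = OCTAVE_CENTERS_HZ
    spl_db: np.ndarray = None
    recording_id: str = ""
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.spl_db = np.asarray(self.spl_db, dtype=float)
        if len(self.centers_hz) != 9 or self.spl_db.shape != (9,):
            raise ValueError("expected exactly 9 octave bands")
        if not np.all(np.isfinite(self.spl_db)):
            raise ValueError("band levels must be finite")


@dataclass
class SessionGain:
    session_id: str
    gain_db: float
    n_pairs: int = 0


# --------------------------------------------------------------------------
# measurement
# --------------------------------------------------------------------------

def octave_spl(signal: np.ndarray, fs: float, band_center_hz: float,
               ref_db: float = FULLSCALE_DB) -> float:
    """SPL (dB re 1 uPa) of ``signal`` in the octave around ``band_center_hz``.

    Band edges are ``center/sqrt(2)`` and ``center*sqrt(2)``; a 6th-order
    Butterworth applied forward-backward isolates the band.
    """
    lo, hi = band_center_hz / np.sqrt(2.0), band_center_hz * np.sqrt(2.0)
    if hi >= fs / 2.0:
        raise ValueError(
            f"octave band at {band_center_hz} Hz exceeds the Nyquist frequency {fs / 2} Hz"
        )
    sos = _sig.butter(6, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = _sig.sosfiltfilt(sos, np.asarray(signal, dtype=float))
    r = float(np.sqrt(np.mean(y * y)))
    return 20.0 * np.log10(max(r, 1e-300)) + ref_db


def octave_levels(signal: np.ndarray, fs: float, ref_db: float = FULLSCALE_DB,
                  recording_id: str = "", timestamp: float = 0.0) -> OctaveBandLevels:
    """All nine standard octave levels of one recording."""
    spl = [octave_spl(signal, fs, c, ref_db) for c in OCTAVE_CENTERS_HZ]
    return OctaveBandLevels(OCTAVE_CENTERS_HZ, np.array(spl), recording_id, timestamp)


# --------------------------------------------------------------------------
# wind -> wave height -> sea state -> predicted level
# --------------------------------------------------------------------------

def wave_height(v_kmh):
    """Wave height (m) from wind speed (km/h): ``h = v * 0.27 / g``.

    The source relation is applied exactly as published, with the wind in
    km/h and g = 9.80665 m/s^2; the resulting mixed units are intentional.
    """
    v = np.asarray(v_kmh, dtype=float)
    if np.any(v < 0):
        raise ValueError("wind speed cannot be negative")
    h = v * 0.27 / STANDARD_GRAVITY
    return float(h) if np.isscalar(v_kmh) else h


def sea_state(h_m):
    """Continuous sea state from wave height via the WMO boundary curve."""
    h = np.asarray(h_m, dtype=float)
    if np.any(h < 0):
        raise ValueError("wave height cannot be negative")
    ss = _H_TO_SS(np.clip(h, 0.0, _WMO_HEIGHTS_M[-1]))
    ss = np.where(h >= _WMO_HEIGHTS_M[-1], 9.0, ss)
    return float(ss) if np.isscalar(h_m) else ss


def sea_state_to_wave_height(ss):
    """Inverse of :func:`sea_state` (continuous states 0-9)."""
    s = np.clip(np.asarray(ss, dtype=float), 0.0, 9.0)
    h = np.interp(s, _SS_DENSE, _H_DENSE)
    return float(h) if np.isscalar(ss) else h


def _wind_ms_from_sea_state(ss) -> np.ndarray:
    """Wind speed (m/s) consistent with the h = v*0.27/g relation."""
    h = sea_state_to_wave_height(ss)
    return np.asarray(h) * STANDARD_GRAVITY / 0.27 / 3.6


def wenz_psd(f_hz, sea_state_value: float, shipping: float = 0.5):
    """Deep-water ambient-noise spectrum level, dB re 1 uPa^2/Hz.

    Fitted analytic approximation of the classical reference curves:
    power sum of turbulence, distant-shipping, wind-driven and thermal
    components.  ``shipping`` in [0, 1] scales the shipping band.
    """
    f = np.asarray(f_hz, dtype=float) / 1000.0  # kHz
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    w = _wind_ms_from_sea_state(sea_state_value)

    t0, t1 = _WENZ["turbulence"]
    s0, s1, s2, s3, s4 = _WENZ["shipping"]
    w0, w1, w2, w3, w4 = _WENZ["wind"]
    h0, h1 = _WENZ["thermal"]

    logf = np.log10(f)
    lt = t0 + t1 * logf
    ls = s0 + s1 * (shipping - 0.5) + s2 * logf + s3 * np.log10(f + s4)
    lw = w0 + w1 * np.sqrt(w) + w2 * logf + w3 * np.log10(f + w4)
    lh = h0 + h1 * logf
    total = 10.0 * np.log10(
        10.0 ** (lt / 10.0) + 10.0 ** (ls / 10.0)
        + 10.0 ** (lw / 10.0) + 10.0 ** (lh / 10.0)
    )
    return float(total) if np.isscalar(f_hz) else total


def wenz_level(sea_state_value: float, band_center_hz: float,
               shipping: float = 0.5) -> float:
    """Predicted octave-band SPL (dB re 1 uPa) at a given sea state.

    Integrates :func:`wenz_psd` over the octave around ``band_center_hz``.
    """
    if not 50.0 <= band_center_hz <= 12800.0:
        raise ValueError(
            f"band centre {band_center_hz} Hz outside the supported 50-12800 Hz range"
        )
    lo, hi = band_center_hz / np.sqrt(2.0), band_center_hz * np.sqrt(2.0)
    f = np.logspace(np.log10(lo), np.log10(hi), 128)
    psd_lin = 10.0 ** (wenz_psd(f, sea_state_value, shipping) / 10.0)
    power = np.trapezoid(psd_lin, f)
    return float(10.0 * np.log10(power))


# --------------------------------------------------------------------------
# session gain and group comparison
# --------------------------------------------------------------------------

def calibrate_gain(measured_db: Sequence[float], predicted_db: Sequence[float],
                   session_id: str = "", min_pairs: int = 10) -> SessionGain:
    """Acquisition-chain gain as ``median(predicted - measured)`` dB.

    The median keeps the estimate robust to recordings contaminated by
    transient sources.  Applied additively: ``measured + gain`` is on the
    predicted (absolute) scale.
    """
    m = np.asarray(measured_db, dtype=float)
    p = np.asarray(predicted_db, dtype=float)
    if m.shape != p.shape:
        raise ValueError("measured and predicted levels must align")
    if m.size < min_pairs:
        raise ValueError(f"need at least {min_pairs} paired recordings, got {m.size}")
    return SessionGain(session_id, float(np.median(p - m)), n_pairs=int(m.size))


def period_compare(levels: np.ndarray, labels: Sequence, centers_hz=OCTAVE_CENTERS_HZ,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-band comparison of octave levels between labelled periods.

    Parameters
    ----------
    levels:
        (n_recordings, n_bands) array of band SPLs.
    labels:
        One group label per recording (e.g. "ferry" / "quiet").

    Returns
    -------
    DataFrame with one row per band: group medians, the difference of the
    first two group medians, the test p-value (rank-sum for two groups,
    Kruskal-Wallis for more) and a significance flag.  Groups with fewer
    than 3 recordings are flagged in the ``underpowered`` column.
    """
    levels = np.asarray(levels, dtype=float)
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels.tolist()))  # preserve order
    if len(groups) < 2:
        raise ValueError("need at least two labelled groups")

    rows = []
    for j, c in enumerate(centers_hz):
        by_group = [levels[labels == g, j] for g in groups]
        report = _stats.compare_groups(
            _stats.GroupedSamples(
                values=np.concatenate(by_group),
                labels=np.concatenate([[g] * len(v) for g, v in zip(groups, by_group)]),
                grouping_name="period",
            ),
            alpha=alpha,
        )
        medians = {f"median_{g}": float(np.median(v)) for g, v in zip(groups, by_group)}
        rows.append({
            "band_hz": c,
            **medians,
            "diff_db": float(np.median(by_group[0]) - np.median(by_group[1])),
            "test": report.test,
            "p_value": report.p_value,
            "significant": report.p_value < alpha,
            "underpowered": any(len(v) < 3 for v in by_group),
        })
    return pd.DataFrame(rows)
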