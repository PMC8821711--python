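"""Click detection: bandpass + Teager-Kaiser energy, plus SPL/SNR measures.

The detector is deliberately tuned for recall: a permissive adaptive
threshold on the smoothed Teager-Kaiser envelope after a bandpass around
12.5 kHz, with a short refractory period.  Precision is recovered later by
the TDoA-track structure and the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .audio import FULLSCALE_DB

__all__ = [
    "DetectionEvent",
    "DetectorConfig",
    "bandpass",
    "teager_kaiser",
    "detect_clicks",
    "click_spl",
    "noise_spl",
    "click_snr",
    "merge_stereo_events",
]

CHANNEL_NAMES = ("east", "west")


@dataclass
class DetectionEvent:
    """One detected transient on one channel."""

    time_s: float
    channel: str  # "east" | "west"
    tk_peak: float
    click_spl_db: float = float("nan")
    noise_spl_db: float = float("nan")
    truncated: bool = False

    @property
    def snr_db(self) -> float:
        return self.click_spl_db - self.noise_spl_db


@dataclass
class DetectorConfig:
    """Detector knobs; defaults follow the documented stand-in rule set."""

    band_hz: tuple = (10_000.0, 15_000.0)
    filter_order: int = 4
    threshold_k: float = 20.0      # threshold = median + k * MAD
    context_s: float = 2.0         # block length for the adaptive statistics
    refractory_s: float = 0.020
    smooth_s: float = 0.0005       # TK envelope moving-average length
    snr_band_hz: tuple = (6_000.0, 15_000.0)
    click_window_s: float = 0.002
    noise_window_s: float = 0.200
    noise_gap_s: float = 0.050
    ref_db: float = FULLSCALE_DB


def bandpass(signal: np.ndarray, low_hz: float, high_hz: float, fs: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass; output has the input's length."""
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] Hz for sample rate {fs} Hz"
        )
    sos = _sig.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, np.asarray(signal, dtype=float))


def teager_kaiser(signal: np.ndarray) -> np.ndarray:
    """Teager-Kaiser energy ``psi[n] = x[n]^2 - x[n-1] x[n+1]``.

    Endpoints are computed on an edge-replicated signal so the output has
    the input's length.  Exactly zero on constant inputs; approximately
    ``A^2 sin^2(omega)`` on a sinusoid of amplitude A.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ValueError("Teager-Kaiser needs at least 3 samples")
    xp = np.concatenate([x[:1], x, x[-1:]])
    return xp[1:-1] ** 2 - xp[:-2] * xp[2:]


def _smooth(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def _detect_channel(x: np.ndarray, fs: float, cfg: DetectorConfig,
                    channel: str) -> list[DetectionEvent]:
    filt = bandpass(x, *cfg.band_hz, fs, order=cfg.filter_order)
    tk = np.maximum(teager_kaiser(filt), 0.0)
    env = _smooth(tk, max(1, int(round(cfg.smooth_s * fs))))

    # adaptive threshold per context block: median + k * MAD
    block = max(1, int(round(cfg.context_s * fs)))
    thresh = np.empty_like(env)
    for start in range(0, env.size, block):
        seg = env[start:start + block]
        med = np.median(seg)
        mad = np.median(np.abs(seg - med))
        thresh[start:start + block] = med + cfg.threshold_k * max(mad, 1e-300)

    above = env > thresh
    if not np.any(above):
        return []

    refractory = max(1, int(round(cfg.refractory_s * fs)))
    events: list[DetectionEvent] = []
    idx = np.flatnonzero(above)
    last_accept = -10 * refractory
    i = 0
    while i < idx.size:
        j = idx[i]
        if j - last_accept < refractory:
            i += 1
            continue
        # take the envelope maximum within the refractory window as the peak
        j_end = min(env.size, j + refractory)
        peak = j + int(np.argmax(env[j:j_end]))
        events.append(DetectionEvent(time_s=peak / fs, channel=channel,
                                     tk_peak=float(env[peak])))
        last_accept = peak
        i += 1
    return events


def detect_clicks(stereo: np.ndarray, fs: float,
                  config: DetectorConfig | None = None) -> list[DetectionEvent]:
    """Detect transients on both channels of a stereo recording.

    Returns one event per TK-envelope excursion per channel, time-sorted,
    with click/noise SPL filled in.  Silent or degenerate input yields an
    empty list.
    """
    cfg = config or DetectorConfig()
    stereo = np.atleast_2d(np.asarray(stereo, dtype=float))
    if stereo.shape[0] < stereo.shape[1]:
        stereo = stereo.T
    if stereo.shape[1] != 2:
        raise ValueError("expected a 2-channel input")
    if np.allclose(stereo, 0.0):
        return []

    events: list[DetectionEvent] = []
    for ch, name in enumerate(CHANNEL_NAMES):
        x = stereo[:, ch]
        ch_events = _detect_channel(x, fs, cfg, name)
        band = bandpass(x, *cfg.snr_band_hz, fs)
        for ev in ch_events:
            ev.click_spl_db, trunc1 = click_spl(band, ev.time_s, fs, cfg)
            ev.noise_spl_db, trunc2 = noise_spl(band, ev.time_s, fs, cfg)
            ev.truncated = trunc1 or trunc2
        events.extend(ch_events)
    events.sort(key=lambda e: e.time_s)
    return events


def click_spl(band_signal: np.ndarray, time_s: float, fs: float,
              cfg: DetectorConfig | None = None,
              prefiltered: bool = True) -> tuple[float, bool]:
    """Click level: RMS over a 2 ms window centred on the click, in dB.

    ``band_signal`` must already be limited to the 6-15 kHz measurement
    band (set ``prefiltered=False`` to have it filtered here).  Returns
    (level_db, truncated_by_file_edge).
    """
    cfg = cfg or DetectorConfig()
    x = np.asarray(band_signal, dtype=float)
    if not prefiltered:
        x = bandpass(x, *cfg.snr_band_hz, fs)
    half = int(round(cfg.click_window_s * fs / 2))
    c = int(round(time_s * fs))
    lo, hi = c - half, c + half
    truncated = lo < 0 or hi > x.size
    seg = x[max(lo, 0):min(hi, x.size)]
    if seg.size == 0:
        return float("nan"), True
    r = float(np.sqrt(np.mean(seg**2)))
    return 20.0 * np.log10(max(r, 1e-300)) + cfg.ref_db, truncated


def noise_spl(band_signal: np.ndarray, time_s: float, fs: float,
              cfg: DetectorConfig | None = None,
              prefiltered: bool = True) -> tuple[float, bool]:
    """Local noise level: RMS of a 200 ms window ending 50 ms pre-click."""
    cfg = cfg or DetectorConfig()
    x = np.asarray(band_signal, dtype=float)
    if not prefiltered:
        x = bandpass(x, *cfg.snr_band_hz, fs)
    hi = int(round((time_s - cfg.noise_gap_s) * fs))
    lo = hi - int(round(cfg.noise_window_s * fs))
    truncated = lo < 0
    seg = x[max(lo, 0):max(hi, 0)]
    if seg.size == 0:
        # fall back to a window after the click near the file start
        lo2 = int(round((time_s + cfg.noise_gap_s) * fs))
        seg = x[lo2:lo2 + int(round(cfg.noise_window_s * fs))]
        truncated = True
    if seg.size == 0:
        return float("nan"), True
    r = float(np.sqrt(np.mean(seg**2)))
    return 20.0 * np.log10(max(r, 1e-300)) + cfg.ref_db, truncated


def click_snr(signal: np.ndarray, event: DetectionEvent | float, fs: float,
              cfg: DetectorConfig | None = None) -> float:
    """SNR of a click: 2 ms click level minus adjacent noise level, dB.

    ``signal`` is one raw channel; the 6-15 kHz measurement band is applied
    here.  ``event`` may be a :class:`DetectionEvent` or a plain time in
    seconds.
    """
    cfg = cfg or DetectorConfig()
    t = event.time_s if isinstance(event, DetectionEvent) else float(event)
    band = bandpass(np.asarray(signal, dtype=float), *cfg.snr_band_hz, fs)
    c, _ = click_spl(band, t, fs, cfg)
    nl, _ = noise_spl(band, t, fs, cfg)
    return c - nl


def merge_stereo_events(events: list[DetectionEvent], max_dt_s: float
                        ) -> list[tuple[DetectionEvent, DetectionEvent | None]]:
    """Pair east/west detections of the same click.

    Events on opposite channels within ``max_dt_s`` (the geometric TDoA
    bound plus slack) are paired; unpaired events are kept with ``None``.
    """
    east = sorted([e for e in events if e.channel == "east"], key=lambda e: e.time_s)
    west = sorted([e for e in events if e.channel == "west"], key=lambda e: e.time_s)
    used = np.zeros(len(west), dtype=bool)
    pairs: list[tuple[DetectionEvent, DetectionEvent | None]] = []
    j = 0
    for ev in east:
        best, best_dt = None, max_dt_s
        for k in range(j, len(west)):
            if west[k].time_s < ev.time_s - max_dt_s:
                j = k + 1
                continue
            if west[k].time_s > ev.time_s + max_dt_s:
                break
            dt = abs(west[k].time_s - ev.time_s)
            if not used[k] and dt <= best_dt:
                best, best_dt = k, dt
        if best is not None:
            used[best] = True
            pairs.append((ev, west[best]))
        else:
            pairs.append((ev, None))
    for k, ev in enumerate(west):
        if not used[k]:
            pairs.append((ev, None))
    pairs.sort(key=lambda p: p[0].time_s)
    return pairs
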