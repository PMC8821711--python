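"""TDoA estimation and the track / passage / individual-count hierarchy.

A moving animal traces a smooth curve in the (time, TDoA) plane; clustering
those curves separates simultaneous animals, and gaps of at least one hour
split the click activity into independent passages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .detection import DetectionEvent, bandpass
from .synthdata import ArrayGeometry

__all__ = [
    "TdoaPoint",
    "Track",
    "Passage",
    "TrackerConfig",
    "tdoa_of_click",
    "build_tracks",
    "segment_passages",
    "count_individuals",
    "PASSAGE_GAP_S",
]

#: silence that separates two passages ("disjoint for at least 1 h")
PASSAGE_GAP_S = 3600.0


@dataclass
class TdoaPoint:
    """One click's inter-channel delay."""

    time_s: float
    tdoa_s: float
    correlation_peak: float = 1.0
    low_confidence: bool = False


@dataclass
class Track:
    """A time-ordered cluster of TDoA points attributed to one animal."""

    points: list[TdoaPoint]
    whale_label: str = ""

    def __post_init__(self) -> None:
        times = [p.time_s for p in self.points]
        if times != sorted(times):
            raise ValueError("track points must be time-ordered")

    @property
    def start_s(self) -> float:
        return self.points[0].time_s

    @property
    def end_s(self) -> float:
        return self.points[-1].time_s

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": [p.time_s for p in self.points],
            "tdoa_s": [p.tdoa_s for p in self.points],
            "correlation_peak": [p.correlation_peak for p in self.points],
            "whale_label": self.whale_label,
        })


@dataclass
class Passage:
    """A contiguous activity period; member tracks are < 1 h apart."""

    tracks: list[Track]

    @property
    def start_s(self) -> float:
        return min(t.start_s for t in self.tracks)

    @property
    def end_s(self) -> float:
        return max(t.end_s for t in self.tracks)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_individuals(self) -> int:
        return count_individuals(self)


@dataclass
class TrackerConfig:
    """Automatic stand-in for the human scatter-plot clustering."""

    max_gap_s: float = 120.0          # max silence inside one track
    max_tdoa_rate_s_per_s: float = 1e-7  # 0.1 ms per second
    tdoa_jitter_s: float = 1e-4       # measurement slack added to the gate
    min_points: int = 20
    min_duration_s: float = 300.0


# --------------------------------------------------------------------------
# TDoA of one click
# --------------------------------------------------------------------------

def tdoa_of_click(
    stereo: np.ndarray,
    event: DetectionEvent | float,
    fs: float,
    max_lag_s: float,
    window_s: float = 0.040,
    band_hz: tuple | None = (5_000.0, 20_000.0),
    min_corr: float = 0.3,
) -> TdoaPoint:
    """Inter-channel delay of one click by windowed cross-correlation.

    The correlation of the west channel against the east channel is
    maximised over lags within ``±max_lag_s``; a positive TDoA means the
    east channel leads (the sound reached the east sensor first).  Peaks
    whose normalised correlation falls below ``min_corr`` are flagged
    low-confidence rather than dropped.
    """
    t = event.time_s if isinstance(event, DetectionEvent) else float(event)
    stereo = np.atleast_2d(np.asarray(stereo, dtype=float))
    if stereo.shape[0] < stereo.shape[1]:
        stereo = stereo.T
    max_lag = int(np.ceil(max_lag_s * fs)) + 1
    half = int(round(window_s * fs / 2))
    c = int(round(t * fs))
    # east template fully inside the west search segment: 'valid'
    # correlation then has no edge truncation, which would bias the peak
    lo_e, hi_e = c - half, c + half
    lo_w, hi_w = lo_e - max_lag, hi_e + max_lag
    if lo_w < 0 or hi_w > stereo.shape[0]:
        return TdoaPoint(time_s=t, tdoa_s=float("nan"),
                         correlation_peak=0.0, low_confidence=True)
    east = stereo[lo_e:hi_e, 0]
    west = stereo[lo_w:hi_w, 1]
    if band_hz is not None and east.size > 12:
        east = bandpass(east, *band_hz, fs)
        west = bandpass(west, *band_hz, fs)

    corr = _sig.correlate(west, east, mode="valid")
    lags = np.arange(-max_lag, max_lag + 1)
    # narrowband clicks give a comb-shaped correlation; the analytic
    # envelope removes the carrier so the peak sits at the true delay
    corr = np.abs(_sig.hilbert(corr))
    denom = np.sqrt(np.sum(east**2) * np.sum(west**2))
    norm = corr / max(denom, 1e-300)
    i = int(np.argmax(norm))
    peak = float(norm[i])
    lag = float(lags[i])
    if 0 < i < norm.size - 1:  # parabolic sub-sample refinement
        y0, y1, y2 = norm[i - 1], norm[i], norm[i + 1]
        denom2 = y0 - 2 * y1 + y2
        if denom2 < 0:
            lag += float(np.clip(0.5 * (y0 - y2) / denom2, -1.0, 1.0))
    return TdoaPoint(
        time_s=t,
        tdoa_s=lag / fs,
        correlation_peak=peak,
        low_confidence=peak < min_corr,
    )


def tdoas_for_scene(stereo: np.ndarray, events, fs: float,
                    geom: ArrayGeometry | None = None,
                    config_window_s: float = 0.040) -> list[TdoaPoint]:
    """TDoA points for all east-channel detections of a scene."""
    geom = geom or ArrayGeometry()
    pts = []
    for ev in events:
        if isinstance(ev, DetectionEvent) and ev.channel != "east":
            continue
        pts.append(tdoa_of_click(stereo, ev, fs, geom.max_tdoa_s,
                                 window_s=config_window_s))
    pts.sort(key=lambda p: p.time_s)
    return pts


# --------------------------------------------------------------------------
# tracks
# --------------------------------------------------------------------------

def build_tracks(points: list[TdoaPoint],
                 config: TrackerConfig | None = None) -> list[Track]:
    """Greedy nearest-neighbour chaining of TDoA points into tracks.

    A point joins the open track whose last point is closest in TDoA,
    provided the time gap is below ``max_gap_s`` and the TDoA jump is
    within ``max_tdoa_rate_s_per_s * dt + tdoa_jitter_s``.  Chains with too
    few points or too short a span are discarded, which kills scattered
    false alarms from noise.
    """
    cfg = config or TrackerConfig()
    pts = sorted((p for p in points if not p.low_confidence),
                 key=lambda p: p.time_s)
    open_tracks: list[list[TdoaPoint]] = []
    done: list[list[TdoaPoint]] = []

    for p in pts:
        # retire tracks that can no longer accept points
        still_open = []
        for tr in open_tracks:
            if p.time_s - tr[-1].time_s > cfg.max_gap_s:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        best, best_d = None, np.inf
        for tr in open_tracks:
            last = tr[-1]
            dt = p.time_s - last.time_s
            gate = cfg.max_tdoa_rate_s_per_s * max(dt, 0.0) + cfg.tdoa_jitter_s
            d = abs(p.tdoa_s - last.tdoa_s)
            if d <= gate and d < best_d:
                best, best_d = tr, d
        if best is not None:
            best.append(p)
        else:
            open_tracks.append([p])

    done.extend(open_tracks)
    tracks = [
        Track(points=tr, whale_label=f"T{i:03d}")
        for i, tr in enumerate(sorted(done, key=lambda tr: tr[0].time_s))
        if len(tr) >= cfg.min_points
        and tr[-1].time_s - tr[0].time_s >= cfg.min_duration_s
    ]
    return tracks


# --------------------------------------------------------------------------
# passages and counts
# --------------------------------------------------------------------------

def segment_passages(tracks: list[Track],
                     gap_s: float = PASSAGE_GAP_S) -> list[Passage]:
    """Group tracks into passages split by >= 1 h of silence.

    Consecutive tracks (by activity time) belong to the same passage when
    the silence between them is strictly shorter than ``gap_s``; a gap of
    exactly one hour splits (strict "disjoint for at least 1 h").
    """
    if not tracks:
        return []
    ordered = sorted(tracks, key=lambda t: t.start_s)
    groups: list[list[Track]] = [[ordered[0]]]
    covered_until = ordered[0].end_s
    for tr in ordered[1:]:
        if tr.start_s - covered_until >= gap_s:
            groups.append([tr])
        else:
            groups[-1].append(tr)
        covered_until = max(covered_until, tr.end_s)
    return [Passage(tracks=g) for g in groups]


def count_individuals(passage: Passage) -> int:
    """Maximum number of simultaneously active tracks in a passage."""
    if not passage.tracks:
        raise ValueError("passage has no tracks")
    events = []
    for tr in passage.tracks:
        events.append((tr.start_s, 1))
        events.append((tr.end_s, -1))
    # starts before ends at the same instant: tracks touching at a point overlap
    events.sort(key=lambda e: (e[0], -e[1]))
    best = cur = 0
    for _, step in events:
        cur += step
        best = max(best, cur)
    return best


def passages_to_frame(passages: list[Passage]) -> pd.DataFrame:
    return pd.DataFrame({
        "passage_id": range(len(passages)),
        "start_s": [p.start_s for p in passages],
        "end_s": [p.end_s for p in passages],
        "duration_s": [p.duration_s for p in passages],
        "n_tracks": [len(p.tracks) for p in passages],
        "n_individuals": [p.n_individuals for p in passages],
    })
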