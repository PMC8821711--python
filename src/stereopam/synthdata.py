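"""Synthetic stereo hydrophone scenes with exact ground truth.

A scene is built from three ingredients whose physics the downstream
pipeline is supposed to recover:

* multipulse clicks — a Gaussian-windowed tone burst repeated ``n_pulses``
  times at lags of one inter-pulse interval, each bounce attenuated by a
  fixed number of dB (:func:`synth_click`);
* straight-ray stereo geometry — per-click channel arrival times from the
  slant ranges to the two hydrophones, which bounds every inter-channel
  delay by ±spacing/c (:func:`simulate_arrivals`);
* spectrum-shaped ambient noise following the deep-water reference model of
  :mod:`stereopam.noise`, with optional broadband boosts inside ferry
  windows (:func:`synth_noise`).

:func:`render_scene` mixes them at calibrated levels (received click level
= SL + G - TL on the scene's dB re 1 uPa scale) and emits the WAV plus
truth tables used as test oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import FULLSCALE_DB, write_wav
from .ipi_size import select_size, size_class
from .noise import wenz_psd
from .range_density import transmission_loss

__all__ = [
    "ClickModel",
    "ArrayGeometry",
    "WhaleSim",
    "NoiseConfig",
    "SceneTruth",
    "synth_click",
    "click_pressure",
    "synth_transient",
    "simulate_arrivals",
    "synth_noise",
    "render_scene",
]


@dataclass
class ClickModel:
    """Multipulse click waveform parameters (bent-horn style pulse train)."""

    n_pulses: int = 3
    ipi_ms: float = 5.0
    pulse_decay_db: float = 6.0
    center_freq_hz: float = 12_000.0
    bandwidth_hz: float = 6_000.0
    pulse_dur_ms: float = 1.0
    source_level_db: float = 200.0  # dB re 1 uPa @ 1 m, on-axis, 2 ms RMS

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.n_pulses > 1 and self.ipi_ms <= self.pulse_dur_ms:
            raise ValueError("ipi_ms must exceed pulse_dur_ms")
        if self.pulse_decay_db < 0:
            raise ValueError("pulse_decay_db must be >= 0")

    @property
    def sigma_s(self) -> float:
        """Gaussian envelope width; the burst spans about +-3 sigma."""
        return self.pulse_dur_ms * 1e-3 / 6.0


@dataclass
class ArrayGeometry:
    """Two-hydrophone array: spacing, depth, axis bearing and sampling."""

    spacing_m: float = 1.83
    depth_m: float = 25.0
    axis_bearing_deg: float = 230.0
    sample_rate_hz: float = 50_000.0
    sound_speed_ms: float = 1500.0

    def __post_init__(self) -> None:
        if self.spacing_m <= 0:
            raise ValueError("spacing must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def max_tdoa_s(self) -> float:
        """Endfire bound on the inter-channel delay, |tau| <= spacing/c."""
        return self.spacing_m / self.sound_speed_ms

    def hydrophone_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """(east, west) positions in metres, ENU-xy with z = depth (down).

        The axis bearing points from the east sensor toward the west one,
        so the east sensor sits on the reciprocal bearing.
        """
        b = np.deg2rad(self.axis_bearing_deg)
        u = np.array([np.sin(b), np.cos(b), 0.0])
        half = 0.5 * self.spacing_m
        down = np.array([0.0, 0.0, self.depth_m])
        east = -u * half + down
        west = u * half + down
        return east, west


@dataclass
class WhaleSim:
    """Scripted whale: a positional track plus regular clicking behaviour."""

    track_t_s: np.ndarray
    track_x_km: np.ndarray
    track_y_km: np.ndarray
    track_depth_m: np.ndarray
    ici_s: float = 1.0
    click_model: ClickModel = field(default_factory=ClickModel)
    active_windows: tuple = ()  # ((start_s, end_s), ...); empty = whole track

    def __post_init__(self) -> None:
        self.track_t_s = np.asarray(self.track_t_s, dtype=float)
        self.track_x_km = np.asarray(self.track_x_km, dtype=float)
        self.track_y_km = np.asarray(self.track_y_km, dtype=float)
        self.track_depth_m = np.asarray(self.track_depth_m, dtype=float)
        if self.ici_s <= 0:
            raise ValueError("inter-click interval must be positive")
        if np.any(self.track_depth_m < 0):
            raise ValueError("depth cannot be negative")

    @classmethod
    def stationary(cls, x_km: float, y_km: float, depth_m: float,
                   duration_s: float, **kw) -> "WhaleSim":
        return cls(np.array([0.0, duration_s]), np.array([x_km, x_km]),
                   np.array([y_km, y_km]), np.array([depth_m, depth_m]), **kw)

    def position_m(self, t_s: np.ndarray) -> np.ndarray:
        """(n, 3) positions in metres (x, y, depth) at times ``t_s``."""
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        x = np.interp(t, self.track_t_s, self.track_x_km) * 1000.0
        y = np.interp(t, self.track_t_s, self.track_y_km) * 1000.0
        z = np.interp(t, self.track_t_s, self.track_depth_m)
        return np.stack([x, y, z], axis=1)

    def click_times(self) -> np.ndarray:
        windows = self.active_windows or ((self.track_t_s[0], self.track_t_s[-1]),)
        times = [np.arange(s, e, self.ici_s) for s, e in windows]
        return np.concatenate(times) if times else np.array([])


@dataclass
class NoiseConfig:
    """Ambient-noise recipe for a scene."""

    sea_state: float = 2.0
    shipping: float = 0.5
    ferry_windows: tuple = ()
    ferry_boost_db: float = 0.0
    ref_db: float = FULLSCALE_DB
    enabled: bool = True


@dataclass
class SceneTruth:
    """Ground-truth tables for one rendered scene."""

    clicks: pd.DataFrame  # one row per emitted click
    whales: pd.DataFrame  # one row per whale: true IPI and size
    meta: dict = field(default_factory=dict)

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.clicks.to_csv(prefix.with_suffix(".clicks.csv"), index=False)
        self.whales.to_csv(prefix.with_suffix(".whales.csv"), index=False)
        prefix.with_suffix(".scene.json").write_text(json.dumps(self.meta, indent=2))


# --------------------------------------------------------------------------
# click synthesis
# --------------------------------------------------------------------------

def _p0_window_rms(model: ClickModel, window_s: float = 2e-3) -> float:
    """RMS of the unscaled first pulse over the standard 2 ms window."""
    sig = model.sigma_s
    t = np.linspace(-window_s / 2, window_s / 2, 4096)
    p = np.exp(-t**2 / (2 * sig**2)) * np.cos(2 * np.pi * model.center_freq_hz * t)
    return float(np.sqrt(np.mean(p**2)))


def click_pressure(t_s: np.ndarray, model: ClickModel) -> np.ndarray:
    """Analytic click waveform evaluated at arbitrary times (seconds).

    The first pulse peaks at t = 0; pulse ``k`` peaks at ``k * ipi`` and is
    attenuated by ``k * pulse_decay_db``.  The waveform is normalised so
    the first pulse has unit RMS over a 2 ms centred window — multiplying
    by ``10**((SL - ref)/20)`` therefore gives a received 2 ms RMS level of
    exactly SL on the ``ref`` dB scale.
    """
    t = np.asarray(t_s, dtype=float)
    sig = model.sigma_s
    out = np.zeros_like(t)
    norm = _p0_window_rms(model)
    for k in range(model.n_pulses):
        tk = t - k * model.ipi_ms * 1e-3
        amp = 10.0 ** (-k * model.pulse_decay_db / 20.0) / norm
        # skip far-away samples; the envelope is negligible beyond 6 sigma
        m = np.abs(tk) < 8 * sig
        out[m] += amp * np.exp(-tk[m] ** 2 / (2 * sig**2)) * np.cos(
            2 * np.pi * model.center_freq_hz * tk[m]
        )
    return out


def synth_click(model: ClickModel, fs: float) -> np.ndarray:
    """Sampled multipulse click starting slightly before the first pulse."""
    if fs < 2.0 * (model.center_freq_hz + model.bandwidth_hz / 2.0):
        raise ValueError(
            f"sample rate {fs} Hz aliases a click centred at "
            f"{model.center_freq_hz} Hz with bandwidth {model.bandwidth_hz} Hz"
        )
    lead = 4 * model.sigma_s
    dur = model.n_pulses * model.ipi_ms * 1e-3 + 2 * lead
    t = np.arange(0.0, dur, 1.0 / fs)
    return click_pressure(t - lead, model)


def synth_transient(rng: np.random.Generator, fs: float, dur_ms: float = 2.0,
                    f_lo: float = 2_000.0, f_hi: float = 20_000.0) -> np.ndarray:
    """Generic single-pulse broadband distractor (boat bang, snapping, ...).

    An exponentially damped narrowband burst at a random carrier — impulsive
    like a click but without the multipulse structure.
    """
    n = int(round(dur_ms * 1e-3 * fs))
    t = np.arange(n) / fs
    f0 = rng.uniform(f_lo, f_hi)
    tau = dur_ms * 1e-3 / 5.0
    x = np.exp(-t / tau) * np.cos(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    return x / max(np.sqrt(np.mean(x**2)), 1e-12)


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def simulate_arrivals(whale: WhaleSim, geom: ArrayGeometry,
                      whale_id: int = 0) -> pd.DataFrame:
    """Per-click truth rows for one whale: ranges, arrival times, TDoA, level.

    Channel arrival time = emission time + slant range / sound speed; the
    TDoA convention is ``t_west - t_east`` (positive when the east sensor
    leads).  Received level uses spherical spreading + absorption from the
    mid-array range, isotropic beam.
    """
    times = whale.click_times()
    h_east, h_west = geom.hydrophone_positions()
    pos = whale.position_m(times)
    r_east = np.linalg.norm(pos - h_east, axis=1)
    r_west = np.linalg.norm(pos - h_west, axis=1)
    c = geom.sound_speed_ms
    t_east = times + r_east / c
    t_west = times + r_west / c
    r_mid = 0.5 * (r_east + r_west)
    rl = whale.click_model.source_level_db - transmission_loss(np.maximum(r_mid, 1.0))
    return pd.DataFrame({
        "whale_id": whale_id,
        "t_emit_s": times,
        "x_m": pos[:, 0], "y_m": pos[:, 1], "depth_m": pos[:, 2],
        "range_east_m": r_east, "range_west_m": r_west,
        "t_east_s": t_east, "t_west_s": t_west,
        "tdoa_s": t_west - t_east,
        "rl_db": rl,
    })


# --------------------------------------------------------------------------
# noise synthesis
# --------------------------------------------------------------------------

def synth_noise(
    sea_state: float,
    duration_s: float,
    fs: float,
    ferry_windows=(),
    ferry_boost_db: float = 0.0,
    shipping: float = 0.5,
    ref_db: float = FULLSCALE_DB,
    seed: int | np.random.Generator = 0,
    f_lo_hz: float = 10.0,
) -> np.ndarray:
    """Gaussian noise whose octave levels follow the ambient-noise model.

    White noise is shaped in the frequency domain so its one-sided PSD (in
    uPa^2/Hz on the ``ref_db`` amplitude scale) equals
    :func:`stereopam.noise.wenz_psd` at the given sea state.  Inside each
    ferry window every band is raised by ``ferry_boost_db``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f_eval = np.maximum(f, f[1] if n > 1 else 1.0)  # avoid log(0) at DC
    psd_db = wenz_psd(f_eval, sea_state, shipping)
    # |H|^2 = S(f) * fs / 2 turns unit-variance white noise into PSD S(f)
    h = np.sqrt(10.0 ** (psd_db / 10.0) * fs / 2.0)
    # the reference spectrum diverges toward infrasound; the lowest octave
    # analysed starts at 35 Hz, so cut everything below f_lo_hz
    h[f < f_lo_hz] = 0.0
    x = np.fft.irfft(spec * h, n=n)
    x *= 10.0 ** (-ref_db / 20.0)  # uPa -> digital full-scale units

    if ferry_boost_db and ferry_windows:
        gain = 10.0 ** (ferry_boost_db / 20.0)
        t = np.arange(n) / fs
        for s, e in ferry_windows:
            x[(t >= s) & (t < e)] *= gain
    return x


# --------------------------------------------------------------------------
# full scene
# --------------------------------------------------------------------------

def render_scene(
    whales: list[WhaleSim],
    geom: ArrayGeometry,
    duration_s: float,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    out_wav: str | Path | None = None,
    out_truth_prefix: str | Path | None = None,
    bit_depth: int = 24,
) -> tuple[np.ndarray, SceneTruth]:
    """Render a stereo scene and its truth tables.

    Returns the (n_samples, 2) float waveform (east = column 0) and a
    :class:`SceneTruth`.  Each click is inserted at its exact per-channel
    arrival time (evaluated analytically, so inter-channel delays are
    sub-sample accurate) with amplitude ``SL - TL(channel range)`` on the
    scene's dB re 1 uPa scale.
    """
    noise = noise or NoiseConfig()
    fs = geom.sample_rate_hz
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)

    data = np.zeros((n, 2))
    if noise.enabled:
        for ch in range(2):
            data[:, ch] = synth_noise(
                noise.sea_state, duration_s, fs,
                ferry_windows=noise.ferry_windows,
                ferry_boost_db=noise.ferry_boost_db,
                shipping=noise.shipping, ref_db=noise.ref_db, seed=rng,
            )

    click_rows, whale_rows = [], []
    for wid, whale in enumerate(whales):
        truth = simulate_arrivals(whale, geom, whale_id=wid)
        # keep only clicks whose arrivals land inside the rendered buffer
        truth = truth[(truth["t_emit_s"] >= 0)
                      & (truth["t_east_s"] < duration_s)
                      & (truth["t_west_s"] < duration_s)]
        click_rows.append(truth)
        model = whale.click_model
        whale_rows.append({
            "whale_id": wid,
            "ipi_ms": model.ipi_ms,
            "size_m": select_size(model.ipi_ms),
            "size_class": size_class(select_size(model.ipi_ms)),
            "ici_s": whale.ici_s,
            "source_level_db": model.source_level_db,
        })

        tail = model.n_pulses * model.ipi_ms * 1e-3 + 8 * model.sigma_s
        for _, row in truth.iterrows():
            for ch, (t_arr, r_ch) in enumerate(
                [(row.t_east_s, row.range_east_m), (row.t_west_s, row.range_west_m)]
            ):
                amp = 10.0 ** (
                    (model.source_level_db - transmission_loss(max(r_ch, 1.0))
                     - noise.ref_db) / 20.0
                )
                i0 = max(0, int(np.floor((t_arr - 6 * model.sigma_s) * fs)))
                i1 = min(n, int(np.ceil((t_arr + tail) * fs)))
                if i1 <= i0:
                    continue
                t_local = np.arange(i0, i1) / fs - t_arr
                data[i0:i1, ch] += amp * click_pressure(t_local, model)

    clicks = (pd.concat(click_rows, ignore_index=True)
              if click_rows else _empty_clicks())
    truth = SceneTruth(
        clicks=clicks,
        whales=pd.DataFrame(whale_rows, columns=[
            "whale_id", "ipi_ms", "size_m", "size_class", "ici_s", "source_level_db",
        ]),
        meta={
            "duration_s": duration_s,
            "sample_rate_hz": fs,
            "seed": seed,
            "ref_db": noise.ref_db,
            "sea_state": noise.sea_state,
            "ferry_boost_db": noise.ferry_boost_db,
            "ferry_windows": [list(wdw) for wdw in noise.ferry_windows],
            "geometry": {
                "spacing_m": geom.spacing_m,
                "depth_m": geom.depth_m,
                "axis_bearing_deg": geom.axis_bearing_deg,
                "sound_speed_ms": geom.sound_speed_ms,
            },
            "n_whales": len(whales),
        },
    )

    if out_wav is not None:
        write_wav(out_wav, data, int(fs), bit_depth=bit_depth)
    if out_truth_prefix is not None:
        truth.write(out_truth_prefix)
    return data, truth


def make_labeled_clips(
    n_clicks: int,
    n_noise: int,
    fs: float = 50_000.0,
    clip_s: float = 0.25,
    sea_state: float = 2.0,
    click_level_db: float = 120.0,
    transient_level_db: float = 115.0,
    transient_fraction: float = 0.5,
    level_jitter_db: float = 8.0,
    ref_db: float = FULLSCALE_DB,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[int], list[str]]:
    """Labeled fixed-length clips for classifier training/evaluation.

    Positive clips hold one multipulse click (random IPI 3-8 ms, random
    centre frequency) around ``click_level_db`` over sea-state noise;
    negatives are noise, half of them spiked with a single-pulse transient
    distractor.  Click and noise levels are jittered by up to
    ``level_jitter_db`` so a classifier cannot key on absolute loudness.

    Returns (clips, labels, class_names) with labels 1 = click, 0 = other.
    """
    rng = np.random.default_rng(seed)
    n_clip = int(round(clip_s * fs))
    clips: list[np.ndarray] = []
    labels: list[int] = []
    classes: list[str] = []

    def jitter() -> float:
        return float(rng.uniform(-level_jitter_db, level_jitter_db))

    for _ in range(n_clicks):
        model = ClickModel(
            ipi_ms=float(rng.uniform(3.0, 8.0)),
            center_freq_hz=float(rng.uniform(9_000.0, 14_000.0)),
        )
        clip = synth_noise(sea_state, clip_s, fs, ref_db=ref_db + jitter(),
                           seed=rng)
        c = synth_click(model, fs) * 10.0 ** ((click_level_db + jitter() - ref_db) / 20.0)
        i0 = n_clip // 2 - int(round(4 * model.sigma_s * fs))
        seg = c[: n_clip - i0]
        clip[i0:i0 + seg.size] += seg
        clips.append(clip)
        labels.append(1)
        classes.append("click")

    for _ in range(n_noise):
        clip = synth_noise(sea_state, clip_s, fs, ref_db=ref_db + jitter(),
                           seed=rng)
        if rng.random() < transient_fraction:
            tr = synth_transient(rng, fs) * 10.0 ** ((transient_level_db + jitter() - ref_db) / 20.0)
            i0 = int(rng.integers(0, n_clip - tr.size))
            clip[i0:i0 + tr.size] += tr
        clips.append(clip)
        labels.append(0)
        classes.append("noise")
    return clips, labels, classes


def _empty_clicks() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "whale_id", "t_emit_s", "x_m", "y_m", "depth_m",
        "range_east_m", "range_west_m", "t_east_s", "t_west_s", "tdoa_s", "rl_db",
    ])
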