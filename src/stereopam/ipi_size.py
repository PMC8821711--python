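"""Inter-pulse-interval (IPI) estimation and body-size conversion.

Sperm-whale clicks contain several decaying replicas of the initial pulse
(the bent-horn reverberation).  The delay between replicas — the IPI — is a
stable per-animal quantity proportional to head length, so it can be turned
into a body-length estimate with published photogrammetry regressions.  Two
regressions are implemented: a quadratic calibrated on juveniles
(:func:`gordon_size`) and a linear one calibrated on large adults
(:func:`growcott_size`), selected by a 4 ms IPI switch (:func:`select_size`).

IPI candidates are extracted per click from two independent views — the real
cepstrum and the analytic-envelope autocorrelation — and combined across a
click train by a trimmed mean (:func:`estimate_ipi`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy.stats import trim_mean

__all__ = [
    "IpiEstimate",
    "cepstrum",
    "autocorrelation",
    "cepstral_ipi",
    "autocorr_ipi",
    "estimate_ipi",
    "gordon_size",
    "growcott_size",
    "select_size",
    "size_class",
    "SIZE_CLASSES",
]

SIZE_CLASSES = ("immature", "adult_female_or_juvenile_male", "adult_male")

#: default quefrency search band for the IPI, milliseconds
DEFAULT_SEARCH_BAND_MS = (2.0, 10.0)


@dataclass
class IpiEstimate:
    """Consensus IPI for one track/click-train and the derived size."""

    ipi_ms: float
    method: str  # "cepstrum" | "autocorrelation" | "consensus"
    size_m: float
    size_class: str
    n_clicks: int
    reliable: bool = True
    method_disagreement_ms: float = 0.0
    per_click_ms: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)


# --------------------------------------------------------------------------
# per-click views
# --------------------------------------------------------------------------

def cepstrum(click: np.ndarray, fs: float) -> np.ndarray:
    """Real cepstrum of a click window.

    Returns an array of the same length as ``click``; index ``q`` is the
    quefrency ``q / fs`` seconds.  A pulse replica at lag ``tau`` produces a
    cepstral peak at quefrency ``tau``.
    """
    x = np.asarray(click, dtype=float)
    if x.size < 8:
        raise ValueError("click window too short for a cepstrum")
    spec = np.fft.rfft(x * np.hanning(x.size), n=2 * x.size)
    log_mag = np.log(np.abs(spec) ** 2 + 1e-300)
    ceps = np.fft.irfft(log_mag)
    return ceps[: x.size]


def autocorrelation(click: np.ndarray, fs: float) -> np.ndarray:
    """Normalised autocorrelation of the analytic envelope (lags >= 0)."""
    x = np.asarray(click, dtype=float)
    env = np.abs(_sig.hilbert(x))
    env = env - env.mean()
    ac = _sig.correlate(env, env, mode="full")[env.size - 1:]
    if ac[0] <= 0:
        return np.zeros_like(ac)
    return ac / ac[0]


def _peak_in_band(seq: np.ndarray, fs: float, band_ms: tuple[float, float]) -> tuple[float, float]:
    """(lag_ms, prominence-like score) of the maximum of ``seq`` in a lag band."""
    lo = max(1, int(round(band_ms[0] * 1e-3 * fs)))
    hi = min(seq.size - 1, int(round(band_ms[1] * 1e-3 * fs)))
    if hi <= lo:
        raise ValueError("search band empty at this sampling rate")
    seg = seq[lo:hi]
    i = int(np.argmax(seg))
    scale = float(np.std(seg)) or 1.0
    score = (float(seg[i]) - float(np.median(seg))) / scale
    return (lo + i) / fs * 1e3, score


def cepstral_ipi(click: np.ndarray, fs: float,
                 band_ms: tuple[float, float] = DEFAULT_SEARCH_BAND_MS) -> tuple[float, float]:
    """Candidate IPI (ms) and peak score from the cepstrum of one click."""
    return _peak_in_band(cepstrum(click, fs), fs, band_ms)


def autocorr_ipi(click: np.ndarray, fs: float,
                 band_ms: tuple[float, float] = DEFAULT_SEARCH_BAND_MS) -> tuple[float, float]:
    """Candidate IPI (ms) and peak score from the envelope autocorrelation."""
    return _peak_in_band(autocorrelation(click, fs), fs, band_ms)


# --------------------------------------------------------------------------
# consensus across a click train
# --------------------------------------------------------------------------

def _prep_click(click: np.ndarray, fs: float, band_hz: tuple[float, float],
                max_ipi_ms: float) -> np.ndarray:
    """Condition one click window before IPI extraction.

    Ambient noise is strongest far below the click band, so the window is
    bandpassed first; it is then trimmed to start just before the strongest
    pulse and to span ~2.5x the maximum searched IPI, which keeps all
    bounces while shedding noise-only samples.
    """
    from .detection import bandpass  # local import to avoid a cycle at load

    x = np.asarray(click, dtype=float)
    lo, hi = band_hz
    if hi < fs / 2 and x.size > 30:
        x = bandpass(x, lo, hi, fs)
    env = np.abs(_sig.hilbert(x))
    peak = int(np.argmax(env))
    start = max(0, peak - int(round(1e-3 * fs)))
    length = int(round((1.0 + 2.5 * max_ipi_ms) * 1e-3 * fs))
    return x[start:start + length]


def estimate_ipi(
    clicks: list[np.ndarray],
    fs: float,
    method: str = "consensus",
    search_band_ms: tuple[float, float] = DEFAULT_SEARCH_BAND_MS,
    n_individuals: int = 1,
    trim: float = 0.2,
    disagreement_tol_ms: float = 0.5,
    min_peak_score: float = 3.0,
    band_hz: tuple[float, float] = (5_000.0, 20_000.0),
) -> IpiEstimate:
    """Consensus IPI over a train of click windows from one track.

    Parameters
    ----------
    clicks:
        Click windows (each at least twice the maximum searched IPI long).
    method:
        "cepstrum", "autocorrelation" or "consensus" (both views pooled).
    n_individuals:
        Number of simultaneous animals in the passage the clicks come from.
        More than two overlapping click trains make per-click IPIs
        unattributable, so such passages are refused.
    trim:
        Fraction trimmed from each tail of the per-click candidate
        distribution before averaging.

    Raises
    ------
    ValueError
        If no clicks are given or ``n_individuals > 2``.
    """
    if n_individuals > 2:
        raise ValueError(
            "IPI estimation is not attempted for passages with more than "
            f"2 individuals (got {n_individuals})"
        )
    if not clicks:
        raise ValueError("need at least one click")
    if method not in ("cepstrum", "autocorrelation", "consensus"):
        raise ValueError(f"unknown method {method!r}")

    ceps_vals, ac_vals = [], []
    for raw in clicks:
        c = _prep_click(raw, fs, band_hz, search_band_ms[1])
        if method in ("cepstrum", "consensus"):
            v, s = cepstral_ipi(c, fs, search_band_ms)
            if s >= min_peak_score:
                ceps_vals.append(v)
        if method in ("autocorrelation", "consensus"):
            v, s = autocorr_ipi(c, fs, search_band_ms)
            if s >= min_peak_score:
                ac_vals.append(v)

    pooled = np.array(ceps_vals + ac_vals)
    reliable = pooled.size >= max(1, len(clicks) // 4)
    if pooled.size >= 4:
        # candidates scattered across the search band mean no stable peak
        q1, q3 = np.percentile(pooled, [25, 75])
        if q3 - q1 > 1.0:
            reliable = False
    disagreement = 0.0
    if ceps_vals and ac_vals:
        disagreement = abs(float(np.median(ceps_vals)) - float(np.median(ac_vals)))
        if disagreement > disagreement_tol_ms:
            reliable = False
    if pooled.size == 0:
        return IpiEstimate(float("nan"), method, float("nan"), "unknown",
                           len(clicks), reliable=False)

    ipi = float(trim_mean(pooled, trim)) if pooled.size > 2 else float(np.median(pooled))
    size = select_size(ipi)
    return IpiEstimate(
        ipi_ms=ipi,
        method=method,
        size_m=size,
        size_class=size_class(size),
        n_clicks=len(clicks),
        reliable=reliable,
        method_disagreement_ms=disagreement,
        per_click_ms=pooled,
    )


# --------------------------------------------------------------------------
# IPI -> size regressions
# --------------------------------------------------------------------------

def gordon_size(ipi_ms: float) -> float:
    """Body length (m) from IPI via the juvenile-calibrated quadratic.

    ``AS = 4.833 + 1.453 * IPI - 0.001 * IPI**2`` with IPI in milliseconds.
    """
    if ipi_ms <= 0:
        raise ValueError("ipi_ms must be positive")
    return 4.833 + 1.453 * ipi_ms - 0.001 * ipi_ms**2


def growcott_size(ipi_ms: float) -> float:
    """Body length (m) from IPI via the adult-calibrated linear fit.

    ``AS = 1.258 * IPI + 5.736`` with IPI in milliseconds.
    """
    if ipi_ms <= 0:
        raise ValueError("ipi_ms must be positive")
    return 1.258 * ipi_ms + 5.736


def select_size(ipi_ms: float) -> float:
    """Size with the 4 ms branch rule.

    The quadratic is used below 4 ms and the linear fit at or above 4 ms
    (the tie at exactly 4.0 ms goes to the linear branch).
    """
    if ipi_ms < 4.0:
        return gordon_size(ipi_ms)
    return growcott_size(ipi_ms)


def select_branch(ipi_ms: float) -> str:
    """Name of the regression branch :func:`select_size` uses."""
    return "gordon" if ipi_ms < 4.0 else "growcott"


def size_class(size_m: float) -> str:
    """Demographic class from body length.

    < 9 m: immature male or female; 9-12 m: adult female or juvenile male;
    > 12 m: adult male.  Boundaries are assigned upward (9.0 m falls in the
    middle class, 12.0 m in the adult-male class).
    """
    if size_m <= 0:
        raise ValueError("size_m must be positive")
    if size_m < 9.0:
        return SIZE_CLASSES[0]
    if size_m < 12.0:
        return SIZE_CLASSES[1]
    return SIZE_CLASSES[2]


def ipi_for_size(size_m: float) -> float:
    """Invert :func:`select_size`: the IPI (ms) that maps to ``size_m``.

    Used by the synthetic generator to script whales of known length.
    """
    if size_m <= 0:
        raise ValueError("size_m must be positive")
    # try the linear (>= 4 ms) branch first
    ipi = (size_m - 5.736) / 1.258
    if ipi >= 4.0:
        return ipi
    # quadratic branch: 4.833 + 1.453 x - 0.001 x^2 = size
    a, b, c = -0.001, 1.453, 4.833 - size_m
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError(f"size {size_m} m unreachable by either regression")
    x = (-b + np.sqrt(disc)) / (2 * a)
    if not 0 < x < 4.0:
        raise ValueError(f"size {size_m} m unreachable by either regression")
    return float(x)
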