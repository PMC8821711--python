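"""Click classifier and the recall-vs-SNR model feeding the range estimate.

A low-complexity CNN (three depthwise convolution blocks with pointwise
mixing, ~10k parameters) scores log-mel-spectrum clips as sperm-whale click
vs anything else.  Its recall as a function of click SNR — measured by
re-mixing clean clicks with locally sampled noise at controlled gains — is
summarised by a fitted sigmoid (:class:`RecallModel`) that the Monte-Carlo
effective-area integration consumes as the detection-probability curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from ._net import DepthwiseConvNet
from .detection import DetectorConfig, bandpass

__all__ = [
    "ClassifierConfig",
    "TrainedClassifier",
    "RecallModel",
    "featurize",
    "mel_filterbank",
    "train",
    "flag_days",
    "recall_vs_snr",
    "fit_sigmoid",
]


@dataclass
class ClassifierConfig:
    """Architecture and feature settings.

    Three depthwise convolution layers with kernel size 7, each followed by
    a pointwise mixing layer; channel widths are chosen so the total
    parameter count stays near the 10k budget (checked by
    :meth:`parameter_count`).
    """

    n_layers: int = 3
    kernel_size: int = 7
    channels: tuple = (64, 48, 48, 48)  # input mels + per-block widths
    target_params: int = 10_000
    class_weights: dict = field(default_factory=lambda: {
        "click": 3.0, "other_cetacean": 10.0, "noise": 1.0,
    })
    # feature settings (unconstrained upstream; chosen for 50 kHz clicks)
    clip_s: float = 0.25
    n_fft: int = 1024
    hop: int = 512
    n_mels: int = 64
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        if len(self.channels) != self.n_layers + 1:
            raise ValueError("channels must list input width plus one per layer")
        if self.channels[0] != self.n_mels:
            raise ValueError("first channel width must equal n_mels")

    def build_net(self, seed: int = 0) -> DepthwiseConvNet:
        net = DepthwiseConvNet(self.channels, self.kernel_size, seed=seed)
        n = net.parameter_count()
        if not self.target_params / 2 <= n <= self.target_params * 2:
            raise ValueError(
                f"parameter count {n} outside 2x of the {self.target_params} budget"
            )
        return net


# --------------------------------------------------------------------------
# features
# --------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, fs: float,
                   f_lo: float = 0.0, f_hi: float | None = None) -> np.ndarray:
    """(n_mels, n_fft//2 + 1) triangular mel filterbank (HTK mel scale)."""
    f_hi = f_hi if f_hi is not None else fs / 2.0
    mels = np.linspace(_hz_to_mel(f_lo), _hz_to_mel(f_hi), n_mels + 2)
    hz = _mel_to_hz(mels)
    bins = np.fft.rfftfreq(n_fft, 1.0 / fs)
    fb = np.zeros((n_mels, bins.size))
    for i in range(n_mels):
        left, center, right = hz[i], hz[i + 1], hz[i + 2]
        up = (bins - left) / max(center - left, 1e-9)
        down = (right - bins) / max(right - center, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def featurize(clip: np.ndarray, fs: float,
              cfg: ClassifierConfig | None = None) -> np.ndarray:
    """Log mel-spectrum of a fixed-length clip, shape (n_mels, n_frames).

    The clip length must equal ``cfg.clip_s * fs`` (within one sample);
    anything else is rejected so batch shapes stay consistent.
    """
    cfg = cfg or ClassifierConfig()
    x = np.asarray(clip, dtype=float)
    expected = int(round(cfg.clip_s * fs))
    if abs(x.size - expected) > 1:
        raise ValueError(f"clip must be {expected} samples at {fs} Hz, got {x.size}")
    x = x[:expected]
    win = np.hanning(cfg.n_fft)
    n_frames = 1 + (x.size - cfg.n_fft) // cfg.hop
    frames = np.lib.stride_tricks.sliding_window_view(x, cfg.n_fft)[::cfg.hop][:n_frames]
    spec = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2
    fb = mel_filterbank(cfg.n_mels, cfg.n_fft, fs)
    mel = spec @ fb.T
    return np.log10(mel.T + cfg.log_floor)


# --------------------------------------------------------------------------
# training / prediction
# --------------------------------------------------------------------------

def _normalize_features(feats: np.ndarray) -> np.ndarray:
    """Per-clip log-mel mean subtraction.

    Removes the overall gain of a clip (a constant in the log domain), so
    classification depends on spectral contrast rather than absolute level
    — essential for recall-vs-SNR curves, where noise is re-mixed at gains
    far outside the training distribution.
    """
    if feats.ndim == 2:
        return feats - feats.mean()
    return feats - feats.mean(axis=(1, 2), keepdims=True)


@dataclass
class TrainedClassifier:
    net: DepthwiseConvNet
    cfg: ClassifierConfig
    feat_mean: float
    feat_std: float
    history: list = field(default_factory=list)

    def _prep(self, feats: np.ndarray) -> np.ndarray:
        return _normalize_features(np.asarray(feats, dtype=float)) / self.feat_std

    def predict_features(self, feats: np.ndarray) -> np.ndarray:
        """Confidences for a (batch, n_mels, n_frames) feature array."""
        return self.net.predict_proba(self._prep(np.asarray(feats, dtype=float)))

    def predict_clips(self, clips: Sequence[np.ndarray], fs: float) -> np.ndarray:
        feats = np.stack([featurize(c, fs, self.cfg) for c in clips])
        return self.predict_features(feats)

    def save(self, path) -> None:
        self.net.save(path)

    def parameter_count(self) -> int:
        return self.net.parameter_count()


def train(
    clips: Sequence[np.ndarray],
    labels: Sequence[int],
    fs: float,
    cfg: ClassifierConfig | None = None,
    sample_classes: Sequence[str] | None = None,
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 64,
    lr: float = 3e-3,
    val_fraction: float = 0.15,
) -> TrainedClassifier:
    """Train the binary click classifier.

    Parameters
    ----------
    labels:
        1 for sperm-whale click, 0 otherwise.
    sample_classes:
        Optional per-sample class names mapped through
        ``cfg.class_weights`` into the weighted binary cross-entropy
        (clicks weighted 3, other cetaceans 10, everything else 1).
    seed:
        Controls initialisation and shuffling; identical seeds give
        bit-identical weights.
    """
    cfg = cfg or ClassifierConfig()
    y = np.asarray(labels, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")

    feats = _normalize_features(np.stack([featurize(c, fs, cfg) for c in clips]))
    mean, std = 0.0, float(feats.std() or 1.0)
    x = feats / std

    if sample_classes is None:
        w = np.where(y == 1, cfg.class_weights.get("click", 1.0), 1.0)
    else:
        w = np.array([cfg.class_weights.get(c, 1.0) for c in sample_classes], dtype=float)

    rng = np.random.default_rng(seed)
    n = x.shape[0]
    n_val = max(1, int(round(val_fraction * n)))
    order = rng.permutation(n)
    val_idx, tr_idx = order[:n_val], order[n_val:]

    net = cfg.build_net(seed=seed)
    clf = TrainedClassifier(net, cfg, mean, std)
    for epoch in range(epochs):
        perm = rng.permutation(tr_idx)
        losses = []
        for start in range(0, perm.size, batch_size):
            b = perm[start:start + batch_size]
            losses.append(net.train_step(x[b], y[b], w[b], lr=lr))
        val_logit = net.forward(x[val_idx])
        val_loss = float(np.mean(
            np.maximum(val_logit, 0) - y[val_idx] * val_logit
            + np.log1p(np.exp(-np.abs(val_logit)))
        ))
        clf.history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_loss": val_loss,
        })
    return clf


def flag_days(confidences_per_day: Mapping[str, Sequence[float]],
              conf_thresh: float = 0.95, count_thresh: int = 40) -> list[str]:
    """Days needing manual validation.

    A day is flagged when strictly more than ``count_thresh`` confidence
    values are strictly above ``conf_thresh``.
    """
    flagged = []
    for day, conf in confidences_per_day.items():
        n_high = int(np.sum(np.asarray(conf, dtype=float) > conf_thresh))
        if n_high > count_thresh:
            flagged.append(day)
    return flagged


# --------------------------------------------------------------------------
# recall vs SNR and the sigmoid model
# --------------------------------------------------------------------------

def _band_rms_db(x: np.ndarray, fs: float, band=(6_000.0, 15_000.0)) -> float:
    y = bandpass(x, *band, fs)
    return 20.0 * np.log10(max(float(np.sqrt(np.mean(y**2))), 1e-300))


def recall_vs_snr(
    clf: TrainedClassifier,
    clicks: Sequence[np.ndarray],
    noise_samples: Sequence[np.ndarray],
    snr_grid_db: Sequence[float],
    fs: float,
    decision_threshold: float = 0.5,
    click_center_s: float | None = None,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Recall at controlled SNRs by re-mixing clean clicks with noise.

    For each clean click and each target SNR, a noise sample is scaled so
    the 2 ms / 6-15 kHz click level minus the noise level equals the target,
    then the (unfiltered) mixture is scored by the classifier.  Recall per
    SNR is the fraction of mixtures at or above ``decision_threshold``.
    Pairs with unusable levels are dropped; empty bins are omitted.
    """
    rng = np.random.default_rng(seed)
    det = DetectorConfig()
    center = click_center_s if click_center_s is not None else clf.cfg.clip_s / 2.0

    points = []
    click_levels = []
    for c in clicks:
        band = bandpass(np.asarray(c, dtype=float), *det.snr_band_hz, fs)
        half = int(round(det.click_window_s * fs / 2))
        mid = int(round(center * fs))
        seg = band[max(0, mid - half):mid + half]
        click_levels.append(20.0 * np.log10(max(float(np.sqrt(np.mean(seg**2))), 1e-300)))

    noise_levels = [_band_rms_db(np.asarray(v, dtype=float), fs, det.snr_band_hz)
                    for v in noise_samples]

    for snr in snr_grid_db:
        mixes = []
        for i, c in enumerate(clicks):
            j = int(rng.integers(len(noise_samples)))
            gain_db = click_levels[i] - snr - noise_levels[j]
            noisy = np.asarray(c, dtype=float) + \
                10.0 ** (gain_db / 20.0) * np.asarray(noise_samples[j], dtype=float)
            mixes.append(noisy)
        conf = clf.predict_clips(mixes, fs)
        points.append((float(snr), float(np.mean(conf >= decision_threshold))))
    return points


@dataclass
class RecallModel:
    """Sigmoid recall curve ``L / (1 + exp(-k (snr - x0)))``."""

    L: float
    x0: float
    k: float
    residual_rms: float = 0.0
    flat: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.L <= 1.0:
            raise ValueError("L must be in (0, 1]")
        if self.k < 0:
            raise ValueError("slope must be nonnegative (recall rises with SNR)")

    def __call__(self, snr_db):
        z = -self.k * (np.asarray(snr_db, dtype=float) - self.x0)
        out = self.L / (1.0 + np.exp(np.clip(z, -500, 500)))
        return float(out) if np.isscalar(snr_db) else out


def fit_sigmoid(points: Sequence[tuple[float, float]]) -> RecallModel:
    """Least-squares sigmoid fit of (snr_db, recall) points.

    Needs at least 4 points; flat data (recall range < 0.05) is rejected
    for slope fitting — all-high recall returns a flagged near-unit plateau
    instead of a meaningless transition.
    """
    pts = [(float(a), float(b)) for a, b in points]
    if len(pts) < 4:
        raise ValueError("need at least 4 (snr, recall) points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(y) < 0.05:
        level = float(np.clip(np.mean(y), 1e-6, 1.0))
        return RecallModel(L=level, x0=float(np.median(x)), k=0.0,
                           residual_rms=float(np.std(y)), flat=True)

    def f(s, L, x0, k):
        return L / (1.0 + np.exp(-k * (s - x0)))

    p0 = (min(1.0, max(y.max(), 0.1)), float(x[np.argmin(np.abs(y - y.max() / 2))]), 0.5)
    popt, _ = curve_fit(f, x, y, p0=p0,
                        bounds=([1e-3, x.min() - 50, 1e-4], [1.0, x.max() + 50, 10.0]),
                        maxfev=20_000)
    resid = float(np.sqrt(np.mean((f(x, *popt) - y) ** 2)))
    return RecallModel(L=float(popt[0]), x0=float(popt[1]), k=float(popt[2]),
                       residual_rms=resid)
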