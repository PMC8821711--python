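"""Shared fixtures: short rendered scenes and a small trained classifier.

Everything is generated at test time from fixed seeds — no binary fixtures
are stored in the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from stereopam import synthdata as sd
from stereopam.detection import DetectorConfig, bandpass


FS = 50_000.0


@pytest.fixture(scope="session")
def geom() -> sd.ArrayGeometry:
    return sd.ArrayGeometry()


@pytest.fixture(scope="session")
def one_whale_scene(geom):
    """12 s scene, one stationary whale 2.9 km NE at 400 m, sea state 2."""
    whale = sd.WhaleSim.stationary(2.0, 2.0, 400.0, 12.0, ici_s=1.0,
                                   click_model=sd.ClickModel(ipi_ms=5.0))
    data, truth = sd.render_scene([whale], geom, 12.0,
                                  sd.NoiseConfig(sea_state=2.0), seed=0)
    return data, truth


@pytest.fixture(scope="session")
def noise_only_scene(geom):
    data, truth = sd.render_scene([], geom, 12.0,
                                  sd.NoiseConfig(sea_state=2.0), seed=1)
    return data, truth


@pytest.fixture(scope="session")
def trained_classifier():
    """Small classifier trained once per session on generated clips."""
    from stereopam.classifier import train

    clips, labels, classes = sd.make_labeled_clips(150, 150, fs=FS, seed=11)
    return train(clips, labels, FS, sample_classes=classes, seed=11, epochs=12)


def make_click_windows(true_ipi_ms: float, snr_db: float, n: int = 50,
                       win_s: float = 0.04, n_pulses: int = 4,
                       seed: int = 7) -> list[np.ndarray]:
    """Click windows in sea-state noise at a controlled 2 ms / 6-15 kHz SNR."""
    rng = np.random.default_rng(seed)
    det = DetectorConfig()
    model = sd.ClickModel(ipi_ms=true_ipi_ms, n_pulses=n_pulses)
    click = sd.synth_click(model, FS)
    nwin = int(win_s * FS)
    out = []
    for _ in range(n):
        noise = sd.synth_noise(2.0, win_s + 0.01, FS, seed=rng)
        band = bandpass(noise, *det.snr_band_hz, FS)
        nl = 20 * np.log10(np.sqrt(np.mean(band**2)))
        amp = 10 ** ((nl + snr_db) / 20)  # click is unit 2 ms RMS
        w = noise[:nwin].copy()
        i0 = int(0.002 * FS)
        seg = click[:nwin - i0]
        w[i0:i0 + seg.size] += amp * seg
        out.append(w)
    return out
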