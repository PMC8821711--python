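"""Generator tests: click structure, geometry, noise spectrum, scene levels."""

import numpy as np
import pytest
from scipy.signal import find_peaks, hilbert

from stereopam import synthdata as sd
from stereopam.noise import octave_spl, wenz_level, OCTAVE_CENTERS_HZ
from stereopam.range_density import transmission_loss

FS = 50_000.0


class TestSynthClick:
    def test_single_pulse_has_no_secondary_autocorr_peak(self):
        c = sd.synth_click(sd.ClickModel(n_pulses=1), FS)
        env = np.abs(hilbert(c))
        ac = np.correlate(env - env.mean(), env - env.mean(), "full")
        ac = ac[ac.size // 2:] / ac.max()
        # beyond the pulse envelope width nothing correlates
        beyond = ac[int(0.002 * FS):]
        assert np.all(beyond < 0.2)

    def test_three_pulses_at_ipi_lags(self):
        c = sd.synth_click(sd.ClickModel(n_pulses=3, ipi_ms=5.0), FS)
        env = np.abs(hilbert(c))
        peaks, _ = find_peaks(env, height=env.max() * 0.05,
                              distance=int(0.002 * FS))
        assert len(peaks) == 3
        gaps_ms = np.diff(peaks) / FS * 1e3
        assert np.allclose(gaps_ms, 5.0, atol=1.0 / FS * 1e3)  # +-1 sample

    def test_decay_6db_halves_rms(self):
        m = sd.ClickModel(n_pulses=3, ipi_ms=5.0, pulse_decay_db=6.0)
        c = np.pad(sd.synth_click(m, FS), (200, 200))
        lead = 200 + int(4 * m.sigma_s * FS)
        w = int(0.002 * FS)

        def rms_at(k):
            i = lead + int(k * 5.0e-3 * FS)
            seg = c[i - w // 2:i + w // 2]
            return np.sqrt(np.mean(seg**2))

        assert rms_at(1) / rms_at(0) == pytest.approx(0.5, rel=0.05)
        assert rms_at(2) / rms_at(1) == pytest.approx(0.5, rel=0.05)

    def test_unit_p0_rms_normalisation(self):
        m = sd.ClickModel()
        c = np.pad(sd.synth_click(m, FS), (200, 200))
        lead = 200 + int(4 * m.sigma_s * FS)
        w = int(0.002 * FS)
        seg = c[lead - w // 2:lead + w // 2]
        assert np.sqrt(np.mean(seg**2)) == pytest.approx(1.0, rel=0.02)

    def test_aliasing_rejected(self):
        with pytest.raises(ValueError, match="alias"):
            sd.synth_click(sd.ClickModel(center_freq_hz=12_000.0), fs=20_000.0)

    def test_duration_covers_all_pulses(self):
        m = sd.ClickModel(n_pulses=5, ipi_ms=7.0)
        c = sd.synth_click(m, FS)
        assert c.size / FS >= 5 * 7.0e-3

    def test_model_invariants(self):
        with pytest.raises(ValueError):
            sd.ClickModel(n_pulses=0)
        with pytest.raises(ValueError):
            sd.ClickModel(ipi_ms=0.5, pulse_dur_ms=1.0)
        with pytest.raises(ValueError):
            sd.ClickModel(pulse_decay_db=-1.0)


class TestSimulateArrivals:
    def test_broadside_whale_zero_tdoa(self, geom):
        # perpendicular to the 230 deg axis through the midpoint: 140 deg
        b = np.deg2rad(140.0)
        whale = sd.WhaleSim.stationary(3.0 * np.sin(b), 3.0 * np.cos(b),
                                       geom.depth_m, 10.0)
        truth = sd.simulate_arrivals(whale, geom)
        assert np.allclose(truth.tdoa_s, 0.0, atol=1e-9)

    def test_endfire_limit(self, geom):
        # far on the axis: |tdoa| -> spacing / c = 1.22 ms
        b = np.deg2rad(230.0)
        whale = sd.WhaleSim.stationary(50.0 * np.sin(b), 50.0 * np.cos(b),
                                       geom.depth_m, 10.0)
        truth = sd.simulate_arrivals(whale, geom)
        assert np.abs(truth.tdoa_s.iloc[0]) == pytest.approx(1.83 / 1500.0,
                                                             rel=1e-4)

    def test_crossing_whale_tdoa_changes_sign_monotonically(self, geom):
        # straight transit through broadside
        t = np.linspace(0, 600, 61)
        b = np.deg2rad(230.0)
        along = np.linspace(-5, 5, 61)  # km along the axis
        whale = sd.WhaleSim(t, along * np.sin(b) + 2 * np.cos(b),
                            along * np.cos(b) - 2 * np.sin(b),
                            np.full(61, 300.0), ici_s=10.0)
        truth = sd.simulate_arrivals(whale, geom)
        tdoa = truth.tdoa_s.to_numpy()
        assert tdoa[0] * tdoa[-1] < 0
        assert np.all(np.diff(tdoa) < 0) or np.all(np.diff(tdoa) > 0)

    def test_tdoa_bound_holds_everywhere(self, geom):
        rng = np.random.default_rng(0)
        for _ in range(20):
            whale = sd.WhaleSim.stationary(rng.uniform(-10, 10),
                                           rng.uniform(-10, 10),
                                           rng.uniform(0, 1500), 5.0)
            truth = sd.simulate_arrivals(whale, geom)
            assert np.all(np.abs(truth.tdoa_s) <= geom.max_tdoa_s + 1e-12)


class TestSynthNoise:
    def test_band_levels_match_model_within_1db(self):
        x = sd.synth_noise(3.0, 12.0, FS, seed=1)
        for fc in OCTAVE_CENTERS_HZ:
            assert octave_spl(x, FS, fc) == pytest.approx(
                wenz_level(3.0, fc), abs=1.0), fc

    def test_zero_boost_indistinguishable(self):
        x = sd.synth_noise(2.0, 10.0, FS, ferry_windows=((0.0, 5.0),),
                           ferry_boost_db=0.0, seed=2)
        a = octave_spl(x[:int(5 * FS)], FS, 800)
        b = octave_spl(x[int(5 * FS):], FS, 800)
        assert a == pytest.approx(b, abs=0.5)

    def test_3db_boost_measured(self):
        x = sd.synth_noise(2.0, 10.0, FS, ferry_windows=((0.0, 5.0),),
                           ferry_boost_db=3.0, seed=2)
        a = octave_spl(x[:int(5 * FS)], FS, 800)
        b = octave_spl(x[int(5 * FS):], FS, 800)
        assert a - b == pytest.approx(3.0, abs=0.5)

    def test_higher_sea_state_louder_low_band(self):
        levels = [octave_spl(sd.synth_noise(ss, 5.0, FS, seed=3), FS, 200)
                  for ss in (1.0, 3.0, 5.0)]
        assert levels[0] < levels[1] < levels[2]

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError):
            sd.synth_noise(2.0, 0.0, FS)


class TestRenderScene:
    def test_empty_whale_list_pure_noise(self, noise_only_scene):
        data, truth = noise_only_scene
        assert len(truth.clicks) == 0
        assert data.shape == (int(12.0 * FS), 2)

    def test_bookkeeping(self, geom, tmp_path):
        whale = sd.WhaleSim.stationary(1.0, 1.0, 300.0, 10.0, ici_s=1.0)
        data, truth = sd.render_scene(
            [whale], geom, 10.0, sd.NoiseConfig(enabled=False), seed=0,
            out_wav=tmp_path / "s.wav", out_truth_prefix=tmp_path / "s")
        assert data.shape[0] == int(10.0 * FS)
        assert (tmp_path / "s.wav").exists()
        assert (tmp_path / "s.clicks.csv").exists()
        assert (tmp_path / "s.scene.json").exists()
        # all rendered clicks have in-scene arrivals
        assert (truth.clicks.t_west_s < 10.0).all()

    def test_received_level_is_sl_minus_tl(self, geom):
        from stereopam.detection import click_snr, click_spl, bandpass, DetectorConfig
        whale = sd.WhaleSim.stationary(2.0, 2.0, 400.0, 8.0, ici_s=1.0)
        data, truth = sd.render_scene([whale], geom, 8.0,
                                      sd.NoiseConfig(enabled=False), seed=0)
        cfg = DetectorConfig()
        band = bandpass(data[:, 0], *cfg.snr_band_hz, FS)
        row = truth.clicks.iloc[2]
        level, _ = click_spl(band, row.t_east_s, FS, cfg)
        expected = 200.0 - transmission_loss(row.range_east_m)
        assert level == pytest.approx(expected, abs=1.0)

    def test_doubling_range_drops_level_by_tl_difference(self, geom):
        from stereopam.detection import click_spl, bandpass, DetectorConfig
        cfg = DetectorConfig()
        levels = {}
        for r_km in (2.0, 4.0):
            whale = sd.WhaleSim.stationary(r_km, 0.0, 100.0, 6.0, ici_s=2.0)
            data, truth = sd.render_scene([whale], geom, 6.0,
                                          sd.NoiseConfig(enabled=False), seed=0)
            band = bandpass(data[:, 0], *cfg.snr_band_hz, FS)
            row = truth.clicks.iloc[1]
            levels[r_km] = (click_spl(band, row.t_east_s, FS, cfg)[0],
                            row.range_east_m)
        tl_diff = transmission_loss(levels[4.0][1]) - transmission_loss(levels[2.0][1])
        assert levels[2.0][0] - levels[4.0][0] == pytest.approx(tl_diff, abs=1.0)


class TestLabeledClips:
    def test_shapes_and_labels(self):
        clips, labels, classes = sd.make_labeled_clips(5, 7, fs=FS, seed=0)
        assert len(clips) == 12
        assert sum(labels) == 5
        assert all(c.size == int(0.25 * FS) for c in clips)
        assert classes.count("click") == 5
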