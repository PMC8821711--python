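"""Sonar-budget terms, Monte-Carlo effective area, habitat area, density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stereopam import range_density as rd
from stereopam.classifier import RecallModel


class TestAbsorption:
    def test_survey_conditions_value(self):
        # 12.5 kHz, 11 C, 38.5 ppt, 500 m, pH 8
        assert rd.absorption(12.5, 11.0, 38.5, 500.0, 8.0) == pytest.approx(
            1.43, abs=0.1)

    def test_vanishes_at_low_frequency(self):
        assert rd.absorption(1e-3) < 1e-4

    def test_increases_with_frequency(self):
        f = np.arange(1.0, 50.0, 2.0)
        a = [rd.absorption(x) for x in f]
        assert np.all(np.diff(a) > 0)

    @pytest.mark.parametrize("kwargs", [
        {"f_khz": -1.0}, {"f_khz": 12.5, "temp_c": 60.0},
        {"f_khz": 12.5, "salinity_ppt": 1.0}, {"f_khz": 12.5, "ph": 3.0},
        {"f_khz": 12.5, "depth_m": -5.0},
    ])
    def test_out_of_model_rejected(self, kwargs):
        with pytest.raises(ValueError):
            rd.absorption(**kwargs)


class TestTransmissionLoss:
    def test_reference_range(self):
        assert rd.transmission_loss(1.0, 1.43) == pytest.approx(0.0, abs=0.01)

    def test_1km(self):
        assert rd.transmission_loss(1000.0, 1.43) == pytest.approx(61.43)

    def test_10km(self):
        assert rd.transmission_loss(10_000.0, 1.43) == pytest.approx(94.3)

    def test_below_1m_rejected(self):
        with pytest.raises(ValueError):
            rd.transmission_loss(0.5)

    @given(st.floats(1.0, 1e5), st.floats(1.0, 1e5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_range(self, r1, r2):
        if r1 < r2:
            assert rd.transmission_loss(r1) < rd.transmission_loss(r2)


class TestBeamGain:
    def test_on_axis_zero(self):
        assert rd.beam_gain(0.0, "piston") == 0.0
        assert rd.beam_gain(0.0, "isotropic") == 0.0

    def test_isotropic_everywhere_zero(self):
        theta = np.linspace(0, np.pi, 20)
        assert np.allclose(rd.beam_gain(theta, "isotropic"), 0.0)

    def test_piston_nonincreasing_to_first_null(self):
        # first null of 2 J1(x)/x at x = 3.83; with ka=10 that is ~22.5 deg
        theta = np.linspace(0, np.arcsin(3.83 / 10.0) * 0.999, 100)
        g = rd.beam_gain(theta, "piston", ka=10.0)
        assert np.all(np.diff(g) <= 1e-9)

    def test_table_model_with_offset(self):
        model = ("table", [0.0, np.pi], [-161.0, -181.0], 161.0)
        assert rd.beam_gain(0.0, model) == pytest.approx(0.0)
        assert rd.beam_gain(np.pi, model) == pytest.approx(-20.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            rd.beam_gain(0.1, "cardioid")

    def test_angle_domain_checked(self):
        with pytest.raises(ValueError):
            rd.beam_gain(-0.1)


class TestSnrBudget:
    def test_worked_example(self):
        assert rd.snr_at_antenna(200.0, 0.0, 94.3, 44.0) == pytest.approx(61.7)

    def test_noise_linearity(self):
        base = rd.snr_at_antenna(200.0, 0.0, 80.0, 40.0)
        assert rd.snr_at_antenna(200.0, 0.0, 80.0, 50.0) == base - 10.0

    def test_zero_when_tl_balances(self):
        assert rd.snr_at_antenna(200.0, -5.0, 155.0, 40.0) == 0.0

    def test_budget_object_recomputes(self):
        b = rd.SnrBudget(200.0, -3.0, 90.0, 45.0, 1000.0, 1.43)
        assert b.snr_db == 200.0 - 3.0 - 90.0 - 45.0


class TestMcEffectiveArea:
    def test_everything_detected(self):
        mc = rd.McConfig(n_emissions=10_000, seed=0)
        res = rd.mc_effective_area(mc, lambda s: np.ones_like(s), nl_db=40.0,
                                   beam_model="isotropic")
        assert res.p == 1.0
        assert res.re_km == pytest.approx(400.0)
        assert res.ae_km2 == pytest.approx(np.pi * 400**2)

    def test_step_recall_matches_geometry(self):
        # shallow emitters, no absorption, isotropic: SNR maps 1-1 to range,
        # so a step at the SNR of 50 km detects exactly the inner disc
        mc = rd.McConfig(n_emissions=100_000, max_depth_m=1.0, seed=3)
        sl, nl, r0 = 200.0, 40.0, 50_000.0
        thresh = sl - 20 * np.log10(r0) - nl
        step = lambda snr: (snr >= thresh).astype(float)
        res = rd.mc_effective_area(mc, step, nl, sl_db=sl,
                                   alpha_db_per_km=0.0, beam_model="isotropic")
        p_true = (50.0 / 400.0) ** 2
        assert abs(res.p - p_true) <= 3 * res.mc_se
        assert res.re_km == pytest.approx(50.0, abs=1.5)

    def test_ae_and_re_identities(self):
        mc = rd.McConfig(n_emissions=20_000, seed=1)
        res = rd.mc_effective_area(mc, RecallModel(0.9, 5.0, 0.8), nl_db=50.0)
        assert res.ae_km2 == pytest.approx(res.a_km2 * res.p, rel=1e-12)
        assert res.re_km == pytest.approx(np.sqrt(res.ae_km2 / np.pi), rel=1e-12)

    def test_seed_reproducibility(self):
        mc = rd.McConfig(n_emissions=20_000, seed=7)
        r1 = rd.mc_effective_area(mc, RecallModel(0.9, 5.0, 0.8), nl_db=50.0)
        r2 = rd.mc_effective_area(mc, RecallModel(0.9, 5.0, 0.8), nl_db=50.0)
        assert r1.p == r2.p
        assert r1.re_km == r2.re_km

    def test_bad_recall_rejected(self):
        mc = rd.McConfig(n_emissions=1_000, seed=0)
        with pytest.raises(ValueError):
            rd.mc_effective_area(mc, lambda s: np.full_like(s, 1.5), nl_db=40.0)

    def test_lognormal_depths_truncated(self):
        mc = rd.McConfig(n_emissions=5_000, depth_model="lognormal", seed=2)
        rng = np.random.default_rng(mc.seed)
        _, depth, _ = rd._sample_emissions(mc, rng)
        assert depth.max() <= 1600.0
        assert 150.0 < np.median(depth) < 800.0  # around 10**2.55 = 354 m

    def test_config_validation(self):
        with pytest.raises(ValueError):
            rd.McConfig(n_emissions=0)
        with pytest.raises(ValueError):
            rd.McConfig(depth_model="beta")


class TestRadiusVsNoise:
    def test_monotone_nonincreasing(self):
        mc = rd.McConfig(n_emissions=50_000, seed=1)
        curve = rd.radius_vs_noise(np.arange(35, 76, 5.0), mc,
                                   RecallModel(0.95, 5.0, 0.8))
        re = [r.re_km for r in curve]
        assert np.all(np.diff(re) <= 0)

    def test_sl_nl_budget_symmetry(self):
        # +6 dB of SL compensates +6 dB of NL exactly (common random numbers)
        mc = rd.McConfig(n_emissions=30_000, seed=4)
        recall = RecallModel(0.95, 5.0, 0.8)
        a = rd.radius_vs_noise([50.0], mc, recall, sl_db=200.0)[0]
        b = rd.radius_vs_noise([56.0], mc, recall, sl_db=206.0)[0]
        assert a.re_km == pytest.approx(b.re_km, rel=1e-12)

    def test_empty_grid(self):
        assert rd.radius_vs_noise([], rd.McConfig(n_emissions=100),
                                  RecallModel(0.9, 5.0, 0.8)) == []


class TestHabitatAreaAndDensity:
    def test_survey_worked_example(self):
        # half the 32.9 km disc, rounded to the printed precision
        area = rd.habitat_area(32.9, 0.5)
        assert round(area, -2) == 1700.0

    def test_full_disc(self):
        assert rd.habitat_area(10.0, 1.0) == pytest.approx(np.pi * 100.0)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            rd.habitat_area(0.0, 0.5)

    def test_density_worked_example(self):
        res = rd.density(422, 147, 1700.0)
        assert round(res.density_per_1000km2, 2) == 1.69

    def test_zero_animals(self):
        assert rd.density(0, 10, 100.0).density_per_1000km2 == 0.0

    def test_linear_in_count(self):
        d1 = rd.density(100, 10, 500.0).density_per_1000km2
        d2 = rd.density(200, 10, 500.0).density_per_1000km2
        assert d2 == pytest.approx(2 * d1)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rd.density(10, 0, 100.0)
        with pytest.raises(ValueError):
            rd.density(-1, 10, 100.0)
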