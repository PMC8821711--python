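"""Classifier: features, training determinism, day flagging, recall model."""

import numpy as np
import pytest

from stereopam import synthdata as sd
from stereopam.classifier import (
    ClassifierConfig,
    RecallModel,
    featurize,
    fit_sigmoid,
    flag_days,
    mel_filterbank,
    recall_vs_snr,
    train,
)

FS = 50_000.0


def _auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney statistic), independent of sklearn."""
    from scipy.stats import rankdata
    labels = np.asarray(labels)
    r = rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    return (r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


class TestFeaturize:
    def test_silence_is_constant_log_floor(self):
        cfg = ClassifierConfig()
        f = featurize(np.zeros(int(0.25 * FS)), FS, cfg)
        assert np.allclose(f, np.log10(cfg.log_floor))

    def test_tone_concentrates_in_matching_mel_band(self):
        cfg = ClassifierConfig()
        t = np.arange(int(0.25 * FS)) / FS
        f = featurize(0.1 * np.sin(2 * np.pi * 12_500 * t), FS, cfg)
        profile = f.mean(axis=1)
        peak_mel = int(np.argmax(profile))
        # expected band: where the filterbank response to 12.5 kHz peaks
        fb = mel_filterbank(cfg.n_mels, cfg.n_fft, FS)
        bin_12k5 = int(round(12_500 / (FS / cfg.n_fft)))
        assert abs(peak_mel - int(np.argmax(fb[:, bin_12k5]))) <= 1

    def test_log_linearity_under_scaling(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.01, int(0.25 * FS))
        f1 = featurize(x, FS)
        f10 = featurize(10 * x, FS)
        assert np.allclose(f10 - f1, 2.0, atol=0.01)  # log10(100)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            featurize(np.zeros(1000), FS)


class TestArchitecture:
    def test_parameter_budget(self):
        net = ClassifierConfig().build_net()
        assert 5_000 <= net.parameter_count() <= 20_000

    def test_three_blocks_kernel7(self):
        cfg = ClassifierConfig()
        assert cfg.n_layers == 3
        assert cfg.kernel_size == 7
        net = cfg.build_net()
        assert net.n_blocks == 3
        assert net.params["dw0"].shape[1] == 7

    def test_inconsistent_channels_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(channels=(64, 48))


class TestTraining:
    def test_high_snr_auc(self, trained_classifier):
        clips, labels, _ = sd.make_labeled_clips(60, 60, fs=FS, seed=99)
        conf = trained_classifier.predict_clips(clips, FS)
        assert _auc(np.array(labels), conf) >= 0.95

    def test_shuffled_labels_chance_auc(self):
        clips, labels, _ = sd.make_labeled_clips(60, 60, fs=FS, seed=5)
        # exactly balanced shuffle: label 1 on half of each true class, so
        # the labels carry zero information about click-ness by construction
        shuffled = [1] * 30 + [0] * 30 + [1] * 30 + [0] * 30
        clf = train(clips, shuffled, FS, seed=0, epochs=6)
        test, tl, _ = sd.make_labeled_clips(40, 40, fs=FS, seed=6)
        auc = _auc(np.array(tl), clf.predict_clips(test, FS))
        # memorizing a balanced random labelling leaves residual variance;
        # the point is distance from the 0.95+ AUC of a real signal
        assert abs(auc - 0.5) <= 0.2

    def test_same_seed_identical_weights(self):
        clips, labels, _ = sd.make_labeled_clips(20, 20, fs=FS, seed=1)
        a = train(clips, labels, FS, seed=42, epochs=2)
        b = train(clips, labels, FS, seed=42, epochs=2)
        for k in a.net.params:
            assert np.array_equal(a.net.params[k], b.net.params[k]), k

    def test_single_class_rejected(self):
        clips, _, _ = sd.make_labeled_clips(4, 0, fs=FS, seed=0)
        with pytest.raises(ValueError):
            train(clips, [1, 1, 1, 1], FS)

    def test_save_load_roundtrip(self, trained_classifier, tmp_path):
        from stereopam._net import DepthwiseConvNet
        path = tmp_path / "model.npz"
        trained_classifier.save(path)
        net = DepthwiseConvNet.load(path)
        for k in net.params:
            assert np.array_equal(net.params[k],
                                  trained_classifier.net.params[k])


class TestFlagDays:
    def test_41_above_threshold_flagged(self):
        assert flag_days({"d": [0.96] * 41}) == ["d"]

    def test_40_above_threshold_not_flagged(self):
        assert flag_days({"d": [0.96] * 40}) == []

    def test_100_below_confidence_not_flagged(self):
        assert flag_days({"d": [0.94] * 100}) == []

    def test_mixed_days(self):
        days = {"a": [0.96] * 50, "b": [0.96] * 10, "c": [0.99] * 41}
        assert flag_days(days) == ["a", "c"]


class TestRecallVsSnr:
    def test_high_snr_plateau_and_low_snr_floor(self, trained_classifier):
        clicks, _, _ = sd.make_labeled_clips(30, 0, fs=FS, seed=21)
        noise, _, _ = sd.make_labeled_clips(0, 15, fs=FS,
                                            transient_fraction=0.0, seed=22)
        pts = recall_vs_snr(trained_classifier, clicks, noise,
                            [-25.0, 25.0], FS, seed=0)
        low, high = pts[0][1], pts[1][1]
        assert high >= 0.9
        assert low <= 0.3

    def test_monotone_after_isotonic_smoothing(self, trained_classifier):
        clicks, _, _ = sd.make_labeled_clips(25, 0, fs=FS, seed=31)
        noise, _, _ = sd.make_labeled_clips(0, 12, fs=FS,
                                            transient_fraction=0.0, seed=32)
        pts = recall_vs_snr(trained_classifier, clicks, noise,
                            np.arange(-20, 26, 5.0), FS, seed=0)
        y = np.array([p[1] for p in pts])
        # pool-adjacent-violators: the isotonic fit must stay close to raw
        iso = np.maximum.accumulate(y)
        assert np.max(iso - y) <= 0.35


class TestSigmoidFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        true = RecallModel(0.9, 5.0, 0.8)
        x = np.linspace(-5, 20, 15)
        y = np.clip(true(x) + rng.normal(0, 0.01, x.size), 0, 1)
        m = fit_sigmoid(list(zip(x, y)))
        assert m.L == pytest.approx(0.9, rel=0.1)
        assert m.x0 == pytest.approx(5.0, rel=0.1)
        assert m.k == pytest.approx(0.8, rel=0.1)

    def test_all_ones_flagged_flat(self):
        m = fit_sigmoid([(0, 1.0), (5, 1.0), (10, 1.0), (15, 1.0)])
        assert m.flat
        assert m.L == pytest.approx(1.0)

    def test_refit_on_own_predictions_idempotent(self):
        m = RecallModel(0.85, 6.0, 0.7)
        x = np.linspace(-5, 20, 12)
        refit = fit_sigmoid([(a, m(a)) for a in x])
        assert refit.L == pytest.approx(m.L, abs=1e-6)
        assert refit.x0 == pytest.approx(m.x0, abs=1e-5)
        assert refit.k == pytest.approx(m.k, abs=1e-5)

    def test_midpoint_is_half_plateau(self):
        m = RecallModel(0.9, 5.0, 0.8)
        assert m(5.0) == pytest.approx(0.45)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid([(0, 0.1), (1, 0.5), (2, 0.9)])

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            RecallModel(1.5, 0.0, 1.0)
        with pytest.raises(ValueError):
            RecallModel(0.9, 0.0, -1.0)
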