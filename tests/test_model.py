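import math

import numpy as np
import pytest

from paduavte.model import (
    FUSED_DIM,
    HEAD_DIM,
    PDCMModel,
    TrainConfig,
    TrainingUnit,
    amplify_negatives,
    classify,
    focal_loss,
    fuse,
    predict_patient,
    train,
)
from paduavte.swm import SwmStats
from paduavte.synth import gen_training_units


class TestFuse:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.h_diag = rng.standard_normal(768)
        self.h_symp = rng.standard_normal(768)
        self.swm = [0.5, 1.0, 0, 0, 0, 0]

    def test_inference_no_dropout(self):
        f = fuse(self.h_diag, self.h_symp, self.swm, dropout_rate=0.5, training=False)
        np.testing.assert_array_equal(f.h_dropouted, f.h_concatenated)

    def test_swm_prepended(self):
        f = fuse(self.h_diag, self.h_symp, self.swm)
        np.testing.assert_array_equal(f.h_swm[:6], self.swm)

    def test_lengths(self):
        f = fuse(self.h_diag, self.h_symp, self.swm)
        assert f.h_concatenated.shape == (FUSED_DIM,)
        assert f.h_swm.shape == (HEAD_DIM,)  # 6 + 2*768 = 1542
        assert HEAD_DIM == 1542

    def test_concatenation_order(self):
        f = fuse(self.h_diag, self.h_symp, self.swm)
        np.testing.assert_array_equal(f.h_concatenated[:768], self.h_diag)
        np.testing.assert_array_equal(f.h_concatenated[768:], self.h_symp)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse(self.h_diag[:100], self.h_symp, self.swm)

    def test_training_dropout_scales(self):
        f = fuse(self.h_diag, self.h_symp, self.swm, dropout_rate=0.5, training=True, rng=np.random.default_rng(1))
        kept = f.h_dropouted != 0
        np.testing.assert_allclose(f.h_dropouted[kept], 2.0 * f.h_concatenated[kept])


class TestClassify:
    def test_zero_params_uniform(self):
        f = fuse(np.zeros(768), np.zeros(768), np.zeros(6))
        scores = classify(f, np.zeros((HEAD_DIM, 6)), np.zeros(6))
        np.testing.assert_allclose(scores, np.full(6, 1 / 6))

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        f = fuse(rng.standard_normal(768), rng.standard_normal(768), np.zeros(6))
        scores = classify(f, rng.standard_normal((HEAD_DIM, 6)), rng.standard_normal(6))
        assert scores.sum() == pytest.approx(1.0, abs=1e-6)

    def test_argmax_shift_invariant(self):
        rng = np.random.default_rng(1)
        f = fuse(rng.standard_normal(768), rng.standard_normal(768), np.zeros(6))
        w = rng.standard_normal((HEAD_DIM, 6))
        b = rng.standard_normal(6)
        a = classify(f, w, b).argmax()
        assert classify(f, w, b + 7.5).argmax() == a

    def test_sigmoid_head(self):
        f = fuse(np.zeros(768), np.zeros(768), np.zeros(6))
        scores = classify(f, np.zeros((HEAD_DIM, 6)), np.zeros(6), head="sigmoid")
        np.testing.assert_allclose(scores, np.full(6, 0.5))


class TestFocalLoss:
    def test_perfect_prediction_zero(self):
        scores = np.array([[1.0, 0, 0, 0, 0, 0]])
        assert focal_loss(scores, [0]) == pytest.approx(0.0, abs=1e-6)

    def test_reduces_to_cross_entropy(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = rng.dirichlet(np.ones(6))
            y = int(rng.integers(6))
            assert focal_loss(p, y, gamma=0.0, alpha=None) == pytest.approx(-math.log(p[y]), rel=1e-9)

    def test_hand_value(self):
        p = np.zeros(6)
        p[2] = 0.9
        p[[0, 1, 3, 4, 5]] = 0.02
        got = focal_loss(p, 2, gamma=2.0)
        assert got == pytest.approx((0.1**2) * (-math.log(0.9)), rel=1e-9)

    def test_non_negative(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.dirichlet(np.ones(6))
            assert focal_loss(p, int(rng.integers(6)), gamma=rng.random() * 4) >= 0

    def test_zero_probability_clamped(self):
        p = np.array([1.0, 0, 0, 0, 0, 0])
        assert np.isfinite(focal_loss(p, 1))

    def test_alpha_scales(self):
        p = np.full(6, 1 / 6)
        base = focal_loss(p, 0, gamma=0.0)
        assert focal_loss(p, 0, gamma=0.0, alpha=[2, 1, 1, 1, 1, 1]) == pytest.approx(2 * base)


def make_units(n_padua=100, n_other=20):
    units = [TrainingUnit(f"diag {i}", ["s"], i % 5) for i in range(n_padua)]
    units += [TrainingUnit(f"other {i}", ["s"], 5) for i in range(n_other)]
    return units


class TestAmplifyNegatives:
    def test_fraction_zero_unchanged(self):
        units = make_units()
        assert amplify_negatives(units, 0.0) == units

    def test_ten_percent_of_100(self):
        units = make_units(100, 20)
        out = amplify_negatives(units, 0.10, seed=0)
        assert len(out) == 130  # 120 originals + floor(0.1 * 100)
        added = out[120:]
        assert all(u.category_label == 5 for u in added)
        assert all(any(m in u.diagnosis_text for m in ("?", "undecided")) for u in added)

    def test_deterministic(self):
        units = make_units()
        assert amplify_negatives(units, 0.1, seed=3) == amplify_negatives(units, 0.1, seed=3)

    def test_fraction_above_one_rejected(self):
        with pytest.raises(ValueError):
            amplify_negatives(make_units(), 1.5)

    def test_markers_required(self):
        with pytest.raises(ValueError):
            amplify_negatives(make_units(), 0.1, markers=[])


class TestTrainConfig:
    def test_defaults_match_reported_protocol(self):
        cfg = TrainConfig()
        assert cfg.max_epochs == 100
        assert cfg.patience == 10
        assert cfg.train_fraction == 0.7
        assert cfg.amplify_fraction == 0.10
        assert "?" in cfg.uncertainty_markers

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            TrainConfig(train_fraction=1.5)

    def test_patience_bound(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=5, patience=10)


class TestTrain:
    def test_single_category_rejected(self, small_bundle):
        _, bundle = small_bundle
        stats = SwmStats(bundle.corpora)
        units = [TrainingUnit("d", ["s"], 0) for _ in range(10)]
        with pytest.raises(ValueError):
            train(units, stats, TrainConfig(seed=0, max_epochs=2, patience=1))

    def test_history_and_early_stopping(self, trained_model):
        model, _, _, _ = trained_model
        assert model.best_epoch is not None
        hist = model.history
        assert len(hist) <= model.config.max_epochs
        if len(hist) < model.config.max_epochs:  # stopped early
            assert len(hist) - model.best_epoch == model.config.patience

    def test_best_checkpoint_is_max_f1(self, trained_model):
        model, _, _, _ = trained_model
        best = max(h["val_f1"] for h in model.history)
        assert model.history[model.best_epoch - 1]["val_f1"] == best

    def test_deterministic_history(self, small_bundle):
        spec, bundle = small_bundle
        units = gen_training_units(spec, bundle)
        stats = SwmStats(bundle.corpora)
        cfg = TrainConfig(seed=11, max_epochs=3, patience=2)
        a = train(units, stats, cfg)
        b = train(units, stats, cfg)
        assert a.history == b.history
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_diagnose_only_ignores_symptoms(self, small_bundle):
        spec, bundle = small_bundle
        units = gen_training_units(spec, bundle)
        stats = SwmStats(bundle.corpora)
        cfg = TrainConfig(seed=11, max_epochs=2, patience=1, mode="diagnose_only")
        model = train(units, stats, cfg)
        u1 = TrainingUnit("some diagnosis text", ["sympcat0n1"], 0)
        u2 = TrainingUnit("some diagnosis text", ["sympcat3n2", "sympcat4n0"], 0)
        np.testing.assert_array_equal(model.predict_scores([u1]), model.predict_scores([u2]))


class TestPredictPatient:
    def test_no_diagnoses_all_false(self, trained_model):
        model, _, _, _ = trained_model
        flags, scores = predict_patient(model, [], ["sympcat0n1"])
        assert flags == [False] * 5
        assert not scores.any()

    def test_flag_follows_argmax(self, trained_model):
        model, _, units, _ = trained_model
        unit = next(u for u in units if u.category_label == 1)
        flags, scores = predict_patient(model, [unit.diagnosis_text], unit.symptom_terms)
        k = int(model.predict_scores([TrainingUnit(unit.diagnosis_text, unit.symptom_terms, 0)]).argmax())
        if k < 5:
            assert flags[k]

    def test_adding_unit_never_unsets(self, trained_model):
        model, _, units, _ = trained_model
        d1 = [units[0].diagnosis_text]
        d2 = d1 + [units[1].diagnosis_text]
        f1, _ = predict_patient(model, d1, units[0].symptom_terms)
        f2, _ = predict_patient(model, d2, units[0].symptom_terms)
        assert all(not a or b for a, b in zip(f1, f2))


class TestPersistence:
    def test_round_trip_bit_exact(self, trained_model, tmp_path):
        model, _, units, _ = trained_model
        model.save(tmp_path / "artifact")
        clone = PDCMModel.load(tmp_path / "artifact")
        np.testing.assert_array_equal(model.predict_scores(units[:10]), clone.predict_scores(units[:10]))
        assert clone.best_epoch == model.best_epoch
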