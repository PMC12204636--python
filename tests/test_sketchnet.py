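"""Fire-module network: construction, gradients, training, condensation."""

import numpy as np
import pytest

from roca import nn
from roca.drawing import PreprocessSpec
from roca.sketchnet import (ConfigError, DataError, NetConfig,
                            ShapeError, TrainSpec, TrainedClassifier,
                            build_model, class_is_correct, class_name_for,
                            default_class_names, drawings_to_arrays,
                            evaluate_classifier, train)
from roca import synth


def _tiny_config(**kw):
    base = dict(input_size=32, stem_channels=8, fire_specs=((4, 8, 8),),
                pool_after=(0,), seed=0)
    base.update(kw)
    return NetConfig(**base)


class TestConfig:
    def test_squeeze_must_be_narrower_than_expands(self):
        with pytest.raises(ConfigError, match="squeeze"):
            _tiny_config(fire_specs=((16, 8, 4),))

    def test_needs_at_least_one_fire_module(self):
        with pytest.raises(ConfigError):
            _tiny_config(fire_specs=())

    def test_duplicate_class_names_rejected(self):
        with pytest.raises(ConfigError):
            _tiny_config(class_names=("a", "a", "b"))

    def test_train_spec_validation_fraction_bounds(self):
        with pytest.raises(ConfigError):
            TrainSpec(validation_fraction=1.0)
        with pytest.raises(ConfigError):
            TrainSpec(epochs=0)


class TestForward:
    def test_softmax_output_is_probability_vector(self):
        model = build_model(_tiny_config())
        rng = np.random.default_rng(0)
        probs = model.predict_proba(rng.random((3, 1, 32, 32)))
        assert probs.shape == (3, 6)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_same_seed_same_initial_parameters(self):
        a = build_model(_tiny_config(seed=5))
        b = build_model(_tiny_config(seed=5))
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_wrong_input_size_raises_shape_error(self):
        model = build_model(_tiny_config())
        with pytest.raises(ShapeError):
            model.logits(np.zeros((1, 1, 48, 48)))

    def test_classification_is_deterministic(self, tiny_trained):
        clf, _, pairs = tiny_trained
        drawing = pairs[0][0]
        a = clf.classify_drawing(drawing)
        b = clf.classify_drawing(drawing)
        assert a == b
        assert a.predicted_class == max(a.probabilities, key=a.probabilities.get)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Finite-difference check of the whole net's parameter gradients."""
        cfg = NetConfig(input_size=16, class_names=("a", "b", "c"),
                        stem_channels=4, fire_specs=((2, 3, 3),), pool_after=(),
                        seed=3)
        model = build_model(cfg)
        rng = np.random.default_rng(1)
        x = rng.random((2, 1, 16, 16))
        y = np.array([0, 2])
        # nudge all parameters (esp. zero biases) off exact ReLU kinks, where
        # the two-sided numeric derivative is legitimately ill-defined
        for p in model.params():
            p.value += rng.normal(0, 0.01, p.value.shape)

        def loss():
            return nn.cross_entropy_grad(model.logits(x), y)[0]

        for p in model.params():
            p.grad[...] = 0.0
        base, grad = nn.cross_entropy_grad(model.logits(x), y)
        model.backward(grad)

        eps = 1e-6
        rng2 = np.random.default_rng(7)
        for p in model.params():
            flat = p.value.reshape(-1)
            for idx in rng2.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert abs(numeric - p.grad.reshape(-1)[idx]) < 1e-5


class TestCondensation:
    def test_mapping_is_total_over_default_classes(self):
        names = default_class_names()
        assert len(names) == 6
        assert {class_is_correct(n) for n in names} == {True, False}
        assert class_is_correct("clock_correct")
        assert not class_is_correct("clock_incorrect")

    def test_class_name_for(self):
        assert class_name_for("cube", True) == "cube_correct"
        assert class_name_for("infinity", False) == "infinity_incorrect"


class TestTraining:
    def test_unknown_label_is_data_error(self):
        model = build_model(_tiny_config())
        x = np.zeros((4, 1, 32, 32))
        with pytest.raises(DataError, match="dog"):
            train(model, x, ["dog"] * 4, TrainSpec(epochs=1, seed=0))

    def test_class_absent_from_training_split_is_data_error(self):
        model = build_model(_tiny_config(class_names=("a", "b")))
        x = np.zeros((4, 1, 32, 32))
        with pytest.raises(DataError, match="absent"):
            train(model, x, ["a"] * 4, TrainSpec(epochs=1, seed=0))

    def test_training_report_is_reproducible(self):
        pairs = synth.generate_labeled_dataset(4, 0.5, seed=8)
        x, labels = drawings_to_arrays(pairs, PreprocessSpec(out_size=32))
        spec = TrainSpec(epochs=2, seed=5)
        _, r1 = train(build_model(_tiny_config(seed=4)), x, labels, spec)
        _, r2 = train(build_model(_tiny_config(seed=4)), x, labels, spec)
        assert r1["val_acc"] == r2["val_acc"]
        assert r1["loss"] == r2["loss"]
        assert r1["nondeterminism_flags"] == []

    def test_learning_beats_multiclass_chance(self, tiny_trained):
        """Held-out accuracy after brief training beats the 1/K chance level."""
        clf, report, _ = tiny_trained
        assert report["final_val_acc"] > 1.0 / 6.0


class TestEvaluationAndCheckpoint:
    def test_perfect_and_flipped_confusions(self):
        from roca.screen_eval import BinaryConfusion, metrics_from_confusion
        perfect = metrics_from_confusion(BinaryConfusion(10, 0, 0, 10))
        assert perfect.accuracy == 1.0
        flipped = metrics_from_confusion(BinaryConfusion(0, 10, 10, 0))
        assert flipped.accuracy == 0.0

    def test_evaluate_classifier_counts_condensed_matches(self, tiny_trained):
        clf, _, pairs = tiny_trained
        res = evaluate_classifier(clf, pairs)
        manual = np.mean([clf.classify_drawing(d).condensed_correct == l.correct
                          for d, l in pairs])
        assert res["overall_condensed_accuracy"] == pytest.approx(manual)
        assert set(res["per_task"]) == {"cube", "infinity", "clock"}

    def test_checkpoint_round_trip(self, tiny_trained, tmp_path):
        clf, _, pairs = tiny_trained
        path = tmp_path / "model.npz"
        clf.save(path)
        loaded = TrainedClassifier.load(path)
        d = pairs[3][0]
        assert loaded.classify_drawing(d) == clf.classify_drawing(d)

    def test_pretrained_hook_restores_weights(self, tiny_trained, tmp_path):
        clf, _, _ = tiny_trained
        path = tmp_path / "warm.npz"
        clf.save(path)
        pairs = synth.generate_labeled_dataset(4, 0.5, seed=77)
        x, labels = drawings_to_arrays(pairs, PreprocessSpec(out_size=32))
        model = build_model(clf.model.config)
        spec = TrainSpec(epochs=1, seed=1, pretrained_source=str(path))
        trained, report = train(model, x, labels, spec)
        assert 0.0 <= report["final_val_acc"] <= 1.0
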