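"""Classifier contracts: model shapes and determinism, patient-level folds,
augmentation behaviour, the weighted-loss closed form, early stopping, and
probability outputs."""

import numpy as np
import pytest

from phasebmd.classifier import (
    AugmentConfig,
    TrainConfig,
    augment,
    build_model,
    compute_class_weights,
    load_checkpoint,
    make_folds,
    predict_slices,
    save_checkpoint,
    train,
    weighted_cross_entropy,
)
from phasebmd.errors import ConfigError, ValidationError
from phasebmd.preprocess import SliceStack

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


def toy_dataset(rng, n_per_class=8, size=64):
    """Linearly separable 3-class toy stacks: a bright square whose position
    encodes the class (mimicking aorta/liver position cues)."""
    data = []
    phases = ("NE", "AR", "PV")
    corners = {0: (4, 4), 1: (4, 40), 2: (40, 4)}
    for k, ph in enumerate(phases):
        for _ in range(n_per_class):
            im = rng.normal(0.0, 0.1, size=(size, size)).astype(np.float32)
            i, j = corners[k]
            im[i : i + 18, j : j + 18] += 2.0
            data.append((SliceStack([im], ["L1"], scan_id="toy"), ph))
    return data


class TestBuildModel:
    def test_compact_maps_image_to_three_logits(self, rng):
        cfg = TrainConfig(seed=3)
        model = build_model(cfg)
        x = rng.normal(size=(2, 1, 224, 224)).astype(np.float32)
        assert model.forward(x).shape == (2, 3)
        assert model.n_params > 0

    def test_same_seed_same_initial_parameters(self):
        a = build_model(TrainConfig(seed=5))
        b = build_model(TrainConfig(seed=5))
        assert all(np.array_equal(x, y) for x, y in zip(a.get_weights(), b.get_weights()))

    def test_dense161_has_161_weighted_layers_and_three_outputs(self, rng):
        model = build_model(TrainConfig(backbone="dense161", seed=0))
        assert model.depth == 161
        x = rng.normal(size=(1, 1, 224, 224)).astype(np.float32)
        assert model.forward(x).shape == (1, 3)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ConfigError):
            TrainConfig(backbone="resnet")


class TestFolds:
    def test_154_patients_split_52_51_51(self):
        folds = make_folds([f"p{i}" for i in range(154)], k=3, seed=1)
        sizes = sorted(np.bincount(list(folds.values())).tolist(), reverse=True)
        assert sizes == [52, 51, 51]

    def test_three_patients_three_singleton_folds(self):
        folds = make_folds(["a", "b", "c"], k=3, seed=0)
        assert sorted(folds.values()) == [0, 1, 2]

    def test_deterministic_under_seed(self):
        pats = [f"p{i}" for i in range(20)]
        assert make_folds(pats, seed=4) == make_folds(pats, seed=4)

    def test_every_patient_in_exactly_one_fold(self):
        pats = [f"p{i}" for i in range(31)]
        folds = make_folds(pats, k=3, seed=2)
        assert set(folds) == set(pats)
        # all scans of a patient inherit its fold: no patient straddles folds
        scan_folds = {f"{p}_{ph}": folds[p] for p in pats for ph in ("NE", "AR", "PV")}
        for p in pats:
            assert len({scan_folds[f"{p}_{ph}"] for ph in ("NE", "AR", "PV")}) == 1

    def test_more_folds_than_patients_rejected(self):
        with pytest.raises(ConfigError):
            make_folds(["a", "b"], k=3, seed=0)


class TestAugment:
    def test_all_switches_off_is_identity(self, rng):
        im = rng.normal(size=(32, 32)).astype(np.float32)
        assert np.array_equal(augment(im, AugmentConfig.none(), seed=0), im)

    def test_horizontal_flip_is_involution(self, rng):
        im = rng.normal(size=(32, 32)).astype(np.float32)
        cfg = AugmentConfig(vflip=False, hflip=True, rotation=False, zoom=False,
                            crop=False, fov=False, p_flip=1.0)
        assert np.array_equal(augment(augment(im, cfg, 1), cfg, 2), im)

    def test_fixed_seed_reproducible(self, rng):
        im = rng.normal(size=(64, 64)).astype(np.float32)
        cfg = AugmentConfig()
        assert np.array_equal(augment(im, cfg, seed=7), augment(im, cfg, seed=7))

    def test_output_shape_preserved_under_all_transforms(self, rng):
        im = rng.normal(size=(64, 64)).astype(np.float32)
        cfg = AugmentConfig(p_flip=1.0, p_geom=1.0)
        for seed in range(5):
            assert augment(im, cfg, seed=seed).shape == (64, 64)


class TestLossAndWeights:
    def test_uniform_logits_balanced_weights_give_ln3(self):
        logits = np.zeros((12, 3), dtype=np.float32)
        y = np.array([0, 1, 2] * 4)
        loss, _ = weighted_cross_entropy(logits, y, np.ones(3))
        assert loss == pytest.approx(np.log(3.0), abs=1e-6)

    def test_equal_class_counts_collapse_weights_to_one(self):
        w = compute_class_weights(np.array([0, 1, 2, 0, 1, 2]))
        assert np.allclose(w, 1.0)

    def test_inverse_frequency_normalized_to_mean_one(self):
        w = compute_class_weights(np.array([0, 0, 0, 0, 1, 1, 2, 2]))
        assert w[1] == w[2] > w[0]
        assert np.mean(w) == pytest.approx(1.0)

    def test_weighted_equals_unweighted_when_balanced(self, rng):
        logits = rng.normal(size=(9, 3)).astype(np.float32)
        y = np.array([0, 1, 2] * 3)
        w = compute_class_weights(y)
        balanced, _ = weighted_cross_entropy(logits, y, w)
        plain, _ = weighted_cross_entropy(logits, y, np.ones(3))
        assert balanced == pytest.approx(plain, abs=1e-9)


class TestTraining:
    CFG = dict(batch_size=24, learning_rate=1e-2, image_size=64,
               augmentation=AugmentConfig.none(), seed=2)

    def test_separable_toy_reaches_perfect_validation_f1(self, rng):
        data = toy_dataset(rng)
        cfg = TrainConfig(max_epochs=40, early_stop_patience=40, **self.CFG)
        model, history = train(data, toy_dataset(rng), cfg)
        assert history["val_f1"].max() == pytest.approx(1.0)

    def test_patience_zero_trains_exactly_one_epoch(self, rng):
        data = toy_dataset(rng, n_per_class=3)
        cfg = TrainConfig(max_epochs=10, early_stop_patience=0, **self.CFG)
        _, history = train(data, data, cfg)
        assert len(history) == 1

    def test_missing_class_rejected(self, rng):
        data = [d for d in toy_dataset(rng, n_per_class=3) if d[1] != "PV"]
        cfg = TrainConfig(max_epochs=1, early_stop_patience=1, **self.CFG)
        with pytest.raises(ValidationError):
            train(data, data, cfg)

    def test_checkpoint_round_trip_preserves_predictions(self, rng, tmp_path):
        data = toy_dataset(rng, n_per_class=3)
        cfg = TrainConfig(max_epochs=2, early_stop_patience=2, **self.CFG)
        model, _ = train(data, data, cfg)
        path = save_checkpoint(model, cfg, tmp_path / "ck.npz", fold=0)
        model2, cfg2, fold = load_checkpoint(path)
        stack = data[0][0]
        assert np.allclose(predict_slices(model, stack), predict_slices(model2, stack))
        assert fold == 0 and cfg2.image_size == 64


class TestPredict:
    def make_model(self):
        return build_model(TrainConfig(image_size=32, seed=0))

    def test_probabilities_on_simplex(self, rng):
        model = self.make_model()
        stack = SliceStack([rng.normal(size=(32, 32)).astype(np.float32) for _ in range(7)],
                           [f"random-{i}" for i in range(7)])
        probs = predict_slices(model, stack)
        assert probs.shape == (7, 3)
        assert np.all(probs >= 0) and np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_image_gives_identical_rows(self, rng):
        model = self.make_model()
        im = rng.normal(size=(32, 32)).astype(np.float32)
        probs = predict_slices(model, SliceStack([im, im.copy()], ["L1", "L2"]))
        assert np.allclose(probs[0], probs[1])

    def test_size_mismatch_rejected(self, rng):
        model = self.make_model()
        stack = SliceStack([rng.normal(size=(64, 64)).astype(np.float32)], ["L1"])
        with pytest.raises(ValidationError):
            predict_slices(model, stack)
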