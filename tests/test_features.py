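"""Tests for preprocessing, augmentation, and the compact convnet."""

import numpy as np
import pytest

from dermao import features as F
from dermao.synthetic import SyntheticImageSpec, gen_image_arrays


SMALL_SPEC = F.CNNSpec(conv_blocks=((4, 3, 1), (8, 3, 1)), feature_dim=16)


def _tiny_images(n_per_class=10, size=32, seed=0):
    spec = SyntheticImageSpec(image_size=(size, size), seed=seed)
    raw, labels, _ = gen_image_arrays(n_per_class, spec)
    pp = F.PreprocessConfig(target_size=(size, size))
    return np.stack([F.preprocess(im, pp) for im in raw]), labels


# ---------------------------------------------------------------------------
# preprocessing

def test_preprocess_unit_normalization_is_exact_without_resize():
    img = np.random.default_rng(0).integers(0, 256, (20, 20, 3), dtype=np.uint8)
    cfg = F.PreprocessConfig(target_size=(20, 20))
    out = F.preprocess(img, cfg)
    assert np.array_equal(out, (img / 255.0).astype(np.float32))


def test_preprocess_resizes_to_target():
    img = np.random.default_rng(1).integers(0, 256, (50, 70, 3), dtype=np.uint8)
    out = F.preprocess(img, F.PreprocessConfig(target_size=(24, 24)))
    assert out.shape == (24, 24, 3)
    assert F.preprocess(np.zeros((24, 24, 3), np.uint8),
                        F.PreprocessConfig(target_size=(24, 24))).max() == 0.0


def test_preprocess_standard_normalization():
    img = np.random.default_rng(2).integers(0, 256, (16, 16, 3), dtype=np.uint8)
    out = F.preprocess(
        img, F.PreprocessConfig(target_size=(16, 16), normalization="standard")
    )
    assert np.allclose(out.mean(axis=(0, 1)), 0.0, atol=1e-5)
    assert np.allclose(out.std(axis=(0, 1)), 1.0, atol=1e-4)


def test_preprocess_rejects_bad_input():
    with pytest.raises(ValueError):
        F.preprocess(np.zeros((5, 5)), F.PreprocessConfig())
    with pytest.raises(ValueError):
        F.preprocess(np.zeros((0, 5, 3)), F.PreprocessConfig())


# ---------------------------------------------------------------------------
# augmentation

IDENTITY_AUG = F.PreprocessConfig(
    rotation_max_degrees=0.0, scale_range=(1.0, 1.0),
    horizontal_flip=False, vertical_flip=False,
)


def test_augment_identity_parameters_change_nothing():
    img = np.random.default_rng(3).integers(0, 256, (16, 16, 3), dtype=np.uint8)
    out = F.augment(img, IDENTITY_AUG, np.random.default_rng(0))
    assert np.array_equal(out, img)


def test_augment_flip_is_an_involution(stub_rng_factory):
    cfg = F.PreprocessConfig(
        rotation_max_degrees=0.0, scale_range=(1.0, 1.0),
        horizontal_flip=True, vertical_flip=False,
    )
    img = np.random.default_rng(4).integers(0, 256, (8, 8, 3), dtype=np.uint8)
    # stub uniforms: the angle/scale draws return their interval midpoints
    # (0 degrees, scale 1), and the single pinned random() < 0.5 flips
    once = F.augment(img, cfg, stub_rng_factory(uniforms=[0.0]))
    assert not np.array_equal(once, img)
    twice = F.augment(once, cfg, stub_rng_factory(uniforms=[0.0]))
    assert np.array_equal(twice, img)


def test_augment_determinism_and_dtype():
    cfg = F.PreprocessConfig(rotation_max_degrees=25.0, scale_range=(0.9, 1.1))
    img = np.random.default_rng(5).integers(0, 256, (32, 32, 3), dtype=np.uint8)
    a = F.augment(img, cfg, np.random.default_rng(8))
    b = F.augment(img, cfg, np.random.default_rng(8))
    assert np.array_equal(a, b)
    assert a.dtype == np.uint8 and a.shape == img.shape


# ---------------------------------------------------------------------------
# convnet mechanics

def test_backprop_matches_directional_numeric_derivative():
    # perturb every parameter along a fixed random direction and compare
    # the numeric derivative with the analytic gradient projection
    model = F.SmallCNN(F.CNNSpec(conv_blocks=((4, 3, 1),), feature_dim=6), seed=0)
    rng = np.random.default_rng(0)
    x = rng.random((4, 8, 8, 3)).astype(np.float32)
    y = np.array([0, 1, 0, 1])

    slots = list(model._param_slots())
    direction = [rng.normal(size=getattr(o, n).shape).astype(np.float32) for n, o in slots]

    _loss, dlogits = F._cross_entropy(model.logits(x, train=True), y)
    model._backward(dlogits)
    analytic = sum(
        float(np.sum(getattr(o, "d" + n) * u)) for (n, o), u in zip(slots, direction)
    )

    eps = 1e-3
    originals = [getattr(o, n).copy() for n, o in slots]
    for (n, o), u, p in zip(slots, direction, originals):
        setattr(o, n, p + eps * u)
    lp = F._cross_entropy(model.logits(x, train=True), y)[0]
    for (n, o), u, p in zip(slots, direction, originals):
        setattr(o, n, p - eps * u)
    lm = F._cross_entropy(model.logits(x, train=True), y)[0]
    numeric = (lp - lm) / (2 * eps)
    assert numeric == pytest.approx(analytic, rel=2e-2)


def test_train_reduces_loss_on_separable_images():
    images, labels = _tiny_images(n_per_class=20)
    cfg = F.TrainConfig(epochs=6, batch_size=16, seed=0)
    _model, history = F.train_cnn(images, labels, SMALL_SPEC, cfg)
    assert history["train_loss"][-1] < history["train_loss"][0]
    assert len(history["train_loss"]) == 6
    assert len(history["val_loss"]) == 6


def test_zero_learning_rate_freezes_parameters():
    images, labels = _tiny_images(n_per_class=6)
    spec = F.CNNSpec(conv_blocks=((4, 3, 1),), feature_dim=8, batch_norm=False)
    cfg = F.TrainConfig(epochs=3, learning_rate=0.0, batch_size=8, seed=1)
    model, history = F.train_cnn(images, labels, spec, cfg)
    fresh = F.SmallCNN(spec, seed=1)
    for (n1, o1), (n2, o2) in zip(model._param_slots(), fresh._param_slots()):
        assert np.array_equal(getattr(o1, n1), getattr(o2, n2))
    assert np.allclose(history["train_loss"], history["train_loss"][0])


def test_training_determinism():
    images, labels = _tiny_images(n_per_class=8)
    cfg = F.TrainConfig(epochs=3, batch_size=8, seed=7)
    _m1, h1 = F.train_cnn(images, labels, SMALL_SPEC, cfg)
    _m2, h2 = F.train_cnn(images, labels, SMALL_SPEC, cfg)
    assert h1["train_loss"] == h2["train_loss"]
    assert h1["val_loss"] == h2["val_loss"]


def test_train_rejects_single_class():
    images, labels = _tiny_images(n_per_class=4)
    with pytest.raises(ValueError):
        F.train_cnn(images[labels == 0], labels[labels == 0], SMALL_SPEC, F.TrainConfig(epochs=1))


def test_extract_features_contract():
    images, labels = _tiny_images(n_per_class=5)
    model, _ = F.train_cnn(images, labels, SMALL_SPEC, F.TrainConfig(epochs=2, seed=0))
    feats = F.extract_features(model, images)
    assert feats.shape == (len(images), SMALL_SPEC.feature_dim)
    # purity: a duplicated image yields an identical feature row
    doubled = np.concatenate([images[:1], images])
    feats2 = F.extract_features(model, doubled)
    assert np.array_equal(feats2[0], feats2[1])
    # determinism in inference mode
    assert np.array_equal(feats, F.extract_features(model, images))


def test_deep_features_separate_the_classes():
    from sklearn.neighbors import KNeighborsClassifier

    accs = []
    n = 40  # per class; 30 train / 10 test each
    for seed in range(10):
        spec = SyntheticImageSpec(image_size=(32, 32), seed=seed)
        raw, labels, _ = gen_image_arrays(n, spec)
        pp = F.PreprocessConfig(target_size=(32, 32))
        images = np.stack([F.preprocess(im, pp) for im in raw])
        train = np.concatenate([np.arange(0, 30), np.arange(n, n + 30)])
        test = np.concatenate([np.arange(30, n), np.arange(n + 30, 2 * n)])
        model, _ = F.train_cnn(
            images[train], labels[train],
            F.CNNSpec(conv_blocks=((8, 3, 1), (16, 3, 1), (32, 3, 1)), feature_dim=32),
            F.TrainConfig(epochs=12, batch_size=20, seed=seed),
        )
        feats = F.extract_features(model, images)
        clf = KNeighborsClassifier(5).fit(feats[train], labels[train])
        accs.append(clf.score(feats[test], labels[test]))
    assert np.median(accs) > 0.7


def test_cnn_spec_validation():
    with pytest.raises(ValueError):
        F.CNNSpec(conv_blocks=())
    with pytest.raises(ValueError):
        F.CNNSpec(feature_dim=1)
    with pytest.raises(ValueError):
        F.CNNSpec(conv_blocks=((8, 4, 1),))  # even kernel
    with pytest.raises(ValueError):
        F.TrainConfig(epochs=0)
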