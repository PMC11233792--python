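"""Model assembly, the training regime and full-scene prediction."""

import numpy as np
import pandas as pd
import pytest

from scshsi.hsi_io import HyperspectralCube
from scshsi.models import (TrainingConfig, build_baseline, build_scs_classifier,
                           predict_labels, predict_map, train_model)
from scshsi.preprocessing import SplitIndices, extract_patches, reduce_bands_fa, \
    stratified_split
from scshsi.scs import SCSLayerConfig
from scshsi.synthetic import SceneSpec, generate_scene, make_spectral_library


def _split_all_train(ps, n_val=0):
    n = ps.n_samples
    idx = np.arange(n)
    return SplitIndices(train=idx[n_val:], val=idx[:n_val], test=idx[:0],
                        fractions=(1.0, 0.0, 0.0), seed=0)


# ------------------------------------------------------------------- assembly


def test_scs_classifier_shapes_and_parameter_count(rng):
    spec = build_scs_classifier((3, 3, 3), 4, SCSLayerConfig(n_units=32))
    model = spec.instantiate(rng)
    # 32 kernels of 27 weights, 32 q + 32 p, dense 32*4 + 4
    assert model.n_parameters() == 32 * 27 + 64 + 32 * 4 + 4 == 1060
    out = model.forward(rng.standard_normal((5, 3, 3, 3)))
    assert out.shape == (5, 4)
    # SCS stage itself is 1x1x32: abs-max-pool degraded to identity
    kinds = [d["type"] for d in spec.architecture]
    assert kinds == ["scs", "flatten", "dense"]


def test_scs_classifier_keeps_pooling_for_larger_patches(rng):
    spec = build_scs_classifier((7, 7, 3), 4, SCSLayerConfig(n_units=8))
    kinds = [d["type"] for d in spec.architecture]
    assert "absmaxpool" in kinds
    model = spec.instantiate(rng)
    assert model.forward(rng.standard_normal((2, 7, 7, 3))).shape == (2, 4)


def test_scs_classifier_degenerate_and_invalid_inputs(rng):
    spec = build_scs_classifier((1, 1, 5), 3, SCSLayerConfig(n_units=4, kernel_size=1))
    model = spec.instantiate(rng)
    assert model.forward(np.ones((2, 1, 1, 5))).shape == (2, 3)
    with pytest.raises(ValueError, match="2 classes"):
        build_scs_classifier((3, 3, 3), 1)
    with pytest.raises(ValueError, match="larger than patch"):
        build_scs_classifier((3, 3, 3), 4, SCSLayerConfig(kernel_size=5))


def test_cnn2d_architecture(rng):
    spec = build_baseline("cnn2d", (3, 3, 3), 4)
    kinds = [d["type"] for d in spec.architecture]
    assert kinds == ["conv2d", "relu", "flatten", "dense", "batchnorm",
                     "relu", "dense"]  # 1x1 after conv: pooling is identity
    model = spec.instantiate(rng)
    assert model.forward(rng.standard_normal((2, 3, 3, 3))).shape == (2, 4)


def test_lenet_architecture_classic_and_adapted(rng, caplog):
    spec = build_baseline("lenet", (32, 32, 1), 10)
    dense_dims = [d["out_dim"] for d in spec.architecture if d["type"] == "dense"]
    assert dense_dims == [120, 84, 10]
    model = spec.instantiate(rng)
    assert model.forward(rng.standard_normal((2, 32, 32, 1))).shape == (2, 10)
    with caplog.at_level("INFO", logger="scshsi.models"):
        small = build_baseline("lenet", (3, 3, 3), 4)
    assert any("same-padding" in r.message for r in caplog.records)
    model = small.instantiate(rng)
    assert model.forward(rng.standard_normal((2, 3, 3, 3))).shape == (2, 4)


def test_unknown_baseline_rejected():
    with pytest.raises(ValueError, match="unknown baseline"):
        build_baseline("xception", (3, 3, 3), 4)


# ------------------------------------------------------------------- training


def test_training_config_defaults_and_validation():
    cfg = TrainingConfig()
    assert (cfg.epochs, cfg.batch_size, cfg.learning_rate) == (50, 256, 0.001)
    assert cfg.optimizer == "adam" and cfg.loss == "softmax_cross_entropy"
    with pytest.raises(ValueError):
        TrainingConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainingConfig(optimizer="sgd")


def test_separable_patchset_is_interpolated(separable_patchset):
    ps = separable_patchset
    split = _split_all_train(ps, n_val=20)
    spec = build_scs_classifier((3, 3, 3), 2, SCSLayerConfig(n_units=32))
    trained = train_model(spec, ps, split, TrainingConfig(seed=0))
    final = trained.history.iloc[-1]
    assert final["train_acc"] == 1.0
    assert final["train_loss"] < trained.history.iloc[0]["train_loss"] / 10
    labels, probs = predict_labels(trained, ps.patches[split.train])
    assert np.array_equal(labels, ps.labels[split.train])
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_training_history_has_one_row_per_epoch(separable_patchset):
    ps = separable_patchset
    trained = train_model(build_scs_classifier((3, 3, 3), 2),
                          ps, _split_all_train(ps, n_val=10),
                          TrainingConfig(epochs=7, seed=1))
    assert list(trained.history["epoch"]) == list(range(7))
    assert {"train_loss", "val_loss", "train_acc", "val_acc"} <= \
        set(trained.history.columns)


def test_identical_seeds_identical_histories(separable_patchset):
    ps = separable_patchset
    split = _split_all_train(ps, n_val=20)
    cfg = TrainingConfig(epochs=5, seed=42)
    spec = build_scs_classifier((3, 3, 3), 2, SCSLayerConfig(n_units=16))
    h1 = train_model(spec, ps, split, cfg).history
    h2 = train_model(spec, ps, split, cfg).history
    pd.testing.assert_frame_equal(h1, h2)


def test_degenerate_training_inputs_rejected(separable_patchset):
    ps = separable_patchset
    spec = build_scs_classifier((3, 3, 3), 2)
    empty = SplitIndices(train=np.array([], dtype=int), val=np.array([], dtype=int),
                         test=np.array([], dtype=int), fractions=(0, 0, 1), seed=0)
    with pytest.raises(ValueError, match="empty"):
        train_model(spec, ps, empty, TrainingConfig(epochs=1))
    single = SplitIndices(train=np.flatnonzero(ps.labels == 0),
                          val=np.array([], dtype=int), test=np.array([], dtype=int),
                          fractions=(1, 0, 0), seed=0)
    with pytest.raises(ValueError, match="single class"):
        train_model(spec, ps, single, TrainingConfig(epochs=1))


def test_predict_labels_edge_cases(separable_patchset):
    ps = separable_patchset
    trained = train_model(build_scs_classifier((3, 3, 3), 2), ps,
                          _split_all_train(ps), TrainingConfig(epochs=1, seed=0))
    labels, probs = predict_labels(trained, np.empty((0, 3, 3, 3)))
    assert labels.shape == (0,) and probs.shape == (0, 2)
    with pytest.raises(ValueError, match="does not match"):
        predict_labels(trained, np.ones((2, 5, 5, 3)))


def test_nearest_cosine_prototype_equivalence(rng):
    """A frozen SCS stage with prototype kernels is nearest-cosine classification."""
    from scshsi import nn
    D, C = 6, 3
    prototypes = rng.uniform(0.1, 1.0, (C, D))
    layer = nn.SCSLayer(in_ch=D, n_units=C, k=1, rng=rng, q_init=0.0,
                        q_trainable=False, p_trainable=False)
    layer.params["W"][...] = prototypes
    layer.q[:] = 0.0
    model = nn.Sequential([layer, nn.Flatten()])
    X = rng.uniform(0.05, 1.0, (40, 1, 1, D))
    scores = model.forward(X)
    got = scores.argmax(axis=1)
    spectra = X[:, 0, 0, :]
    cos = (spectra @ prototypes.T) / (
        np.linalg.norm(spectra, axis=1, keepdims=True) *
        np.linalg.norm(prototypes, axis=1))
    assert np.array_equal(got, cos.argmax(axis=1))


# ---------------------------------------------------------------- scene level


@pytest.fixture(scope="module")
def trained_scene_model():
    spec = SceneSpec(seed=5)
    library = make_spectral_library(C=4, B=30, separation=10.0, seed=5)
    cube, mask = generate_scene(spec, library)
    reduced = reduce_bands_fa(cube, 3, seed=5)
    ps = extract_patches(reduced, mask, s=3)
    split = stratified_split(ps, seed=5)
    trained = train_model(build_scs_classifier(ps.patches.shape[1:], 4),
                          ps, split, TrainingConfig(seed=5))
    _, truth = generate_scene(SceneSpec(dims=spec.dims, labeled_fraction=1.0,
                                        seed=5), library)
    return trained, reduced, truth


def test_predicted_map_covers_grid_and_recovers_interior(trained_scene_model):
    trained, reduced, truth = trained_scene_model
    pred = predict_map(trained, reduced, s=3)
    assert pred.shape == truth.shape
    # interior pixels: full 3x3 neighborhood shares the focal class
    t = truth.labels
    interior = np.ones_like(t, dtype=bool)
    interior[[0, -1], :] = interior[:, [0, -1]] = False
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            interior[1:-1, 1:-1] &= (t[1 + di:t.shape[0] - 1 + di,
                                       1 + dj:t.shape[1] - 1 + dj] == t[1:-1, 1:-1])
    agree = (pred.labels[interior] == t[interior]).mean()
    assert agree >= 0.95


def test_uniform_cube_predicts_a_single_class(trained_scene_model):
    trained, _, _ = trained_scene_model
    uniform = HyperspectralCube(data=np.ones((10, 10, 3)) * 0.5)
    pred = predict_map(trained, uniform, s=3, padding="mirror")
    assert len(np.unique(pred.labels)) == 1


def test_predict_map_band_mismatch(trained_scene_model):
    trained, _, _ = trained_scene_model
    with pytest.raises(ValueError, match="bands"):
        predict_map(trained, HyperspectralCube(data=np.ones((8, 8, 7))), s=3)
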