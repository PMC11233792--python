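"""Band reduction, patch extraction and stratified splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scshsi.hsi_io import HyperspectralCube, LabelMask
from scshsi.preprocessing import (extract_patches, extract_patches_full,
                                  reduce_bands_fa, stratified_split)

# ------------------------------------------------------------ factor analysis


def test_fa_returns_requested_band_count(default_scene):
    cube, _, _, _ = default_scene
    out = reduce_bands_fa(cube, n_factors=3, seed=0)
    assert out.shape == (64, 64, 3)
    # each output band standardized over the scene
    flat = out.data.reshape(-1, 3)
    assert np.allclose(flat.mean(axis=0), 0, atol=1e-9)
    assert np.allclose(flat.std(axis=0), 1, atol=1e-9)


def test_fa_recovers_a_two_factor_model(rng):
    # spectra = loadings @ factors + tiny noise: 2 factors explain ~everything
    M, N, B = 20, 20, 15
    factors = rng.standard_normal((M * N, 2))
    loadings = rng.standard_normal((2, B))
    flat = factors @ loadings + 1e-3 * rng.standard_normal((M * N, B))
    flat += rng.uniform(1, 3, B)  # band offsets
    cube = HyperspectralCube(data=flat.reshape(M, N, B))
    out = reduce_bands_fa(cube, n_factors=2, seed=0)
    scores = out.data.reshape(-1, 2)
    z = (flat - flat.mean(0)) / flat.std(0)
    # regress standardized spectra on the 2 factor scores
    coef, *_ = np.linalg.lstsq(scores, z, rcond=None)
    resid = z - scores @ coef
    explained = 1 - resid.var() / z.var()
    assert explained >= 0.99


def test_fa_rejects_degenerate_inputs():
    flat_cube = HyperspectralCube(data=np.full((5, 5, 4), 3.0))
    with pytest.raises(ValueError, match="nonzero variance"):
        reduce_bands_fa(flat_cube, n_factors=2)
    cube = HyperspectralCube(data=np.random.default_rng(0).uniform(0, 1, (4, 4, 3)))
    with pytest.raises(ValueError, match="exceeds band count"):
        reduce_bands_fa(cube, n_factors=5)


def test_fa_invariant_to_bandwise_affine_rescaling(rng):
    data = rng.uniform(0, 1, (16, 16, 8))
    a = rng.uniform(0.5, 4.0, 8)
    b = rng.uniform(-2, 2, 8)
    out1 = reduce_bands_fa(HyperspectralCube(data=data), 3, seed=1)
    out2 = reduce_bands_fa(HyperspectralCube(data=data * a + b), 3, seed=1)
    for k in range(3):
        r = np.corrcoef(out1.data[..., k].ravel(), out2.data[..., k].ravel())[0, 1]
        assert abs(r) >= 0.999


def test_fa_band_selection_mode_returns_original_bands(default_scene):
    cube, _, _, _ = default_scene
    out = reduce_bands_fa(cube, n_factors=3, seed=0, mode="select")
    flat = cube.data.reshape(-1, cube.n_bands)
    sel = out.data.reshape(-1, 3)
    # every selected band must be an exact column of the source cube
    for k in range(3):
        assert any(np.array_equal(sel[:, k], flat[:, b])
                   for b in range(cube.n_bands))


def test_fa_warns_on_zero_variance_band(rng, caplog):
    data = rng.uniform(0, 1, (8, 8, 5))
    data[..., 2] = 7.0
    with caplog.at_level("WARNING", logger="scshsi.preprocessing"):
        reduce_bands_fa(HyperspectralCube(data=data), 2, seed=0)
    assert any("zero-variance" in r.message for r in caplog.records)


# ------------------------------------------------------------------- patches


def test_corner_patch_zero_padding(rng):
    data = rng.uniform(1, 2, (5, 5, 2))
    labels = np.zeros((5, 5), dtype=int)
    labels[0, 0] = 1
    mask = LabelMask(labels=labels, class_names=["a"])
    ps = extract_patches(HyperspectralCube(data=data), mask, s=3, padding="zero")
    assert ps.n_samples == 1
    patch = ps.patches[0]
    assert np.all(patch[0, :, :] == 0) and np.all(patch[:, 0, :] == 0)
    assert np.array_equal(patch[1, 1], data[0, 0])
    assert ps.labels[0] == 0 and tuple(ps.coords[0]) == (0, 0)


def test_patch_count_equals_labeled_pixels(rng):
    data = rng.uniform(0, 1, (8, 8, 3))
    labels = np.zeros((8, 8), dtype=int)
    flat_idx = rng.choice(64, size=17, replace=False)
    labels[np.unravel_index(flat_idx, (8, 8))] = rng.integers(1, 4, 17)
    mask = LabelMask(labels=labels, class_names=["a", "b", "c"])
    ps = extract_patches(HyperspectralCube(data=data), mask, s=3)
    assert ps.n_samples == 17


def test_s1_patches_are_focal_spectra(default_scene):
    cube, mask, _, _ = default_scene
    ps = extract_patches(cube, mask, s=1)
    coords = mask.labeled_coords()
    assert np.array_equal(ps.patches[:, 0, 0, :], cube.data[coords[:, 0], coords[:, 1]])


def test_patch_centers_reproduce_spectra(default_scene):
    cube, mask, _, _ = default_scene
    for padding in ("zero", "mirror"):
        ps = extract_patches(cube, mask, s=3, padding=padding)
        centers = ps.patches[:, 1, 1, :]
        assert np.array_equal(centers, cube.data[ps.coords[:, 0], ps.coords[:, 1]])


def test_patch_parameter_validation(default_scene):
    cube, mask, _, _ = default_scene
    with pytest.raises(ValueError, match="odd"):
        extract_patches(cube, mask, s=4)
    empty = LabelMask(labels=np.zeros((64, 64), dtype=int), class_names=["a"])
    with pytest.raises(ValueError, match="no labeled pixels"):
        extract_patches(cube, empty, s=3)
    small = LabelMask(labels=np.ones((5, 5), dtype=int), class_names=["a"])
    with pytest.raises(ValueError, match="does not match"):
        extract_patches(cube, small, s=3)


def test_full_scene_patches_cover_every_pixel(default_scene):
    cube, _, _, _ = default_scene
    patches = extract_patches_full(cube, s=3)
    assert patches.shape == (64 * 64, 3, 3, 30)
    assert np.array_equal(patches[:, 1, 1, :].reshape(64, 64, 30), cube.data)


# --------------------------------------------------------------------- split


def _patchset_with_counts(counts):
    from scshsi.preprocessing import PatchSet
    labels = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
    n = len(labels)
    return PatchSet(patches=np.zeros((n, 1, 1, 1)), coords=np.zeros((n, 2), int),
                    labels=labels, s=1,
                    class_names=[f"c{i}" for i in range(len(counts))])


def test_split_is_15_15_70_per_class():
    ps = _patchset_with_counts([100, 100, 100, 100])
    sp = stratified_split(ps, (0.15, 0.15, 0.70), seed=3)
    for cls in range(4):
        assert (ps.labels[sp.train] == cls).sum() == 15
        assert (ps.labels[sp.val] == cls).sum() == 15
        assert (ps.labels[sp.test] == cls).sum() == 70


def test_split_largest_remainder_rounding():
    ps = _patchset_with_counts([7])
    # strict mode not triggered: 7 >= 3
    sp = stratified_split(ps, (0.15, 0.15, 0.70), seed=0)
    assert (len(sp.train), len(sp.val), len(sp.test)) == (1, 1, 5)


def test_split_deterministic_for_fixed_seed():
    ps = _patchset_with_counts([40, 25, 33])
    sp1 = stratified_split(ps, seed=11)
    sp2 = stratified_split(ps, seed=11)
    for k in ("train", "val", "test"):
        assert np.array_equal(sp1.as_dict()[k], sp2.as_dict()[k])
    sp3 = stratified_split(ps, seed=12)
    assert not np.array_equal(sp1.train, sp3.train)


@given(counts=st.lists(st.integers(3, 60), min_size=1, max_size=5),
       seed=st.integers(0, 100))
@settings(max_examples=40, deadline=None)
def test_split_partitions_disjoint_and_exhaustive(counts, seed):
    ps = _patchset_with_counts(counts)
    sp = stratified_split(ps, seed=seed)
    merged = np.concatenate([sp.train, sp.val, sp.test])
    assert len(merged) == ps.n_samples
    assert len(np.unique(merged)) == ps.n_samples
    # per-class counts within 1 of fraction * class size
    for cls, c in enumerate(counts):
        for part, f in zip((sp.train, sp.val, sp.test), (0.15, 0.15, 0.70)):
            got = (ps.labels[part] == cls).sum()
            assert abs(got - f * c) <= 1


def test_split_tiny_class_goes_to_train(caplog):
    ps = _patchset_with_counts([20, 2])
    with caplog.at_level("WARNING", logger="scshsi.preprocessing"):
        sp = stratified_split(ps, seed=0)
    assert (ps.labels[sp.train] == 1).sum() == 2
    assert any("assigning all to train" in r.message for r in caplog.records)
    with pytest.raises(ValueError, match="cannot stratify"):
        stratified_split(ps, seed=0, strict=True)


def test_split_rejects_bad_fractions():
    ps = _patchset_with_counts([10])
    with pytest.raises(ValueError, match="fractions"):
        stratified_split(ps, (0.5, 0.5, 0.5), seed=0)
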