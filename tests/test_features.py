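"""VOR / PBM / LEP / DTL extractors against brute-force oracles."""

import numpy as np
import pytest

from brainmorph import (
    DTLExtractor,
    HogConfig,
    LEPExtractor,
    PBMExtractor,
    VORExtractor,
    extract_features,
    extract_lep,
    extract_pbm,
    extract_vor,
    hog_slice,
    make_patch_grid,
)
from brainmorph.features import FeatureError, center_fit
from brainmorph.volumes import BrainMask, Parcellation, synthetic_parcellation

from conftest import toy_maps


# --------------------------------------------------------------------------
# VOR
# --------------------------------------------------------------------------


def test_vor_matches_voxel_loop_oracle():
    rng = np.random.default_rng(1)
    gm = rng.random((8, 8, 8)) * 0.9
    labels = np.zeros((8, 8, 8), dtype=np.int32)
    labels[:4] = 1
    labels[4:, :4] = 2
    labels[4:, 4:, :4] = 3
    parc = Parcellation(labels=labels, n_regions=3)
    fv = extract_vor(toy_maps(gm), parc)
    total = 0.0
    sums = np.zeros(3)
    for idx in np.ndindex(gm.shape):
        total += gm[idx]
        if labels[idx] > 0:
            sums[labels[idx] - 1] += gm[idx]
    np.testing.assert_allclose(fv.values, sums / total, rtol=1e-12)


def test_vor_uniform_gm_gives_region_count_fractions():
    mask = np.zeros((10, 10, 10), dtype=bool)
    mask[2:8, 2:8, 2:8] = True
    parc = synthetic_parcellation(BrainMask(mask=mask), n_regions=4, seed=0)
    gm = np.where(mask, 0.7, 0.0)
    fv = extract_vor(toy_maps(gm), parc)
    sizes = parc.region_sizes()
    np.testing.assert_allclose(fv.values, sizes / mask.sum(), rtol=1e-12)
    assert fv.values.sum() == pytest.approx(1.0)


def test_vor_zero_gm_raises():
    labels = np.ones((4, 4, 4), dtype=np.int32)
    parc = Parcellation(labels=labels, n_regions=1)
    with pytest.raises(FeatureError, match="zero"):
        extract_vor(toy_maps(np.zeros((4, 4, 4))), parc)


def test_vor_nonnegative_bounded(default_parc, one_subject_maps):
    parc, _ = default_parc
    fv = extract_vor(one_subject_maps, parc)
    assert fv.dim == 116
    assert (fv.values >= 0).all() and (fv.values <= 1).all()
    # features sum to the GM fraction covered by the parcellation
    gm = one_subject_maps.gm.astype(np.float64)
    covered = float(gm[parc.labels > 0].sum() / gm.sum())
    assert fv.values.sum() == pytest.approx(covered, rel=1e-10)


# --------------------------------------------------------------------------
# PBM
# --------------------------------------------------------------------------


def test_pbm_matches_blockwise_voxel_loop():
    rng = np.random.default_rng(2)
    gm = rng.random((32, 32, 16)) * 0.8
    grid = make_patch_grid((32, 32, 16), (32, 32, 16), 16)
    fv = extract_pbm(toy_maps(gm), grid)
    assert fv.dim == 4
    expected = np.zeros(4)
    for i in range(2):
        for j in range(2):
            block = gm[16 * i : 16 * (i + 1), 16 * j : 16 * (j + 1), :]
            expected[grid.patch_index(i, j, 0)] = block.sum()
    np.testing.assert_allclose(fv.values, expected / gm.sum(), rtol=1e-12)


def test_pbm_features_sum_to_one_when_gm_inside_crop():
    grid = make_patch_grid((48, 48, 48), (32, 32, 32), 16)
    # GM strictly inside the centered crop window [8, 40)
    gm = np.zeros((48, 48, 48))
    gm[12:36, 12:36, 12:36] = 0.5
    fv = extract_pbm(toy_maps(gm), grid)
    assert fv.values.sum() == pytest.approx(1.0, rel=1e-12)
    assert ((fv.values >= 0) & (fv.values <= 1)).all()


def test_pbm_translation_permutes_patch_features():
    grid = make_patch_grid((48, 32, 16), (48, 32, 16), 16)
    gm = np.zeros((48, 32, 16))
    rng = np.random.default_rng(3)
    blob = rng.random((16, 16, 16)) * 0.9
    gm[0:16, 0:16, :] = blob
    shifted = np.zeros_like(gm)
    shifted[16:32, 0:16, :] = blob
    f0 = extract_pbm(toy_maps(gm), grid).values
    f1 = extract_pbm(toy_maps(shifted), grid).values
    src, dst = grid.patch_index(0, 0, 0), grid.patch_index(1, 0, 0)
    assert f0[src] == pytest.approx(f1[dst], rel=1e-12)
    assert f0[src] > 0
    assert f1[src] == 0.0


def test_pbm_default_dim(one_subject_maps):
    fv = extract_pbm(one_subject_maps)
    assert fv.dim == 864


# --------------------------------------------------------------------------
# HOG / LEP
# --------------------------------------------------------------------------


def _oracle_cell_histograms(img, n_orient=9, cell=8):
    """Centered-gradient orientation histogram per cell, no block normalization."""
    g_row = np.zeros_like(img)
    g_col = np.zeros_like(img)
    g_row[1:-1, :] = img[2:, :] - img[:-2, :]
    g_col[:, 1:-1] = img[:, 2:] - img[:, :-2]
    mag = np.hypot(g_row, g_col)
    ang = np.rad2deg(np.arctan2(g_row, g_col)) % 180
    bins = np.minimum((ang / (180 / n_orient)).astype(int), n_orient - 1)
    hist = np.zeros((img.shape[0] // cell, img.shape[1] // cell, n_orient))
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            hist[i // cell, j // cell, bins[i, j]] += mag[i, j]
    return hist


def test_hog_constant_slice_is_zero():
    assert np.all(hog_slice(np.full((16, 16), 0.37)) == 0)


def test_hog_descriptor_length_is_36():
    rng = np.random.default_rng(4)
    assert hog_slice(rng.random((16, 16))).shape == (36,)
    assert HogConfig().n_features == 36


def test_hog_wrong_shape_rejected():
    with pytest.raises(FeatureError, match="shape"):
        hog_slice(np.zeros((8, 8)))


@pytest.mark.parametrize("transpose", [False, True])
def test_hog_step_edge_energy_in_gradient_bin(transpose):
    """A step edge concentrates energy in the bin of its gradient direction."""
    img = np.zeros((16, 16))
    img[:, 8:] = 1.0
    if transpose:
        img = img.T
    desc = hog_slice(img, HogConfig(block_norm="L2")).reshape(2, 2, 9)
    oracle = _oracle_cell_histograms(img)
    assert np.argmax(desc.sum(axis=(0, 1))) == np.argmax(oracle.sum(axis=(0, 1)))
    # support and proportions agree with the unnormalized oracle per block
    o_flat = oracle.ravel()
    d_flat = desc.ravel()
    np.testing.assert_allclose(
        d_flat, o_flat / np.linalg.norm(o_flat), atol=1e-6
    )


def test_lep_single_patch_matches_slice_loop():
    rng = np.random.default_rng(5)
    gm = rng.random((16, 16, 16)) * 0.9
    grid = make_patch_grid((16, 16, 16), (16, 16, 16), 16)
    fv = extract_lep(toy_maps(gm), grid)
    assert fv.dim == 108
    cfg = HogConfig()
    expected = []
    for axis in (2, 1, 0):  # axial, coronal, sagittal
        descs = [hog_slice(np.take(gm, s, axis=axis), cfg) for s in range(16)]
        expected.append(np.mean(descs, axis=0))
    np.testing.assert_allclose(fv.values, np.concatenate(expected), rtol=1e-12)


def test_lep_constant_volume_is_zero():
    grid = make_patch_grid((32, 32, 16), (32, 32, 16), 16)
    fv = extract_lep(toy_maps(np.full((32, 32, 16), 0.4)), grid)
    assert np.all(fv.values == 0)
    assert fv.dim == 36 * 3 * 4


def test_lep_bitwise_deterministic():
    rng = np.random.default_rng(6)
    gm = rng.random((32, 32, 16)) * 0.9
    grid = make_patch_grid((32, 32, 16), (32, 32, 16), 16)
    a = extract_lep(toy_maps(gm), grid).values
    b = extract_lep(toy_maps(gm), grid).values
    np.testing.assert_array_equal(a, b)


# --------------------------------------------------------------------------
# DTL
# --------------------------------------------------------------------------


def test_dtl_feature_dimension_and_spatial_shape():
    rng = np.random.default_rng(7)
    gm = rng.random((160, 192, 128)) * 0.8
    ext = DTLExtractor(seed=0).fit([toy_maps(gm)])
    fmap = ext.feature_map(toy_maps(gm))
    assert fmap.shape == (5, 6, 4, 64)
    assert ext.transform_one(toy_maps(gm)).shape == (7680,)


def test_dtl_zero_input_zero_features():
    gm = np.zeros((40, 40, 40))
    ext = DTLExtractor(seed=1).fit([toy_maps(gm)])
    assert np.all(ext.transform_one(toy_maps(gm)) == 0)


def test_dtl_seeded_weights_deterministic():
    rng = np.random.default_rng(8)
    gm = rng.random((40, 40, 40)) * 0.9
    a = DTLExtractor(seed=5).fit([toy_maps(gm)]).transform_one(toy_maps(gm))
    b = DTLExtractor(seed=5).fit([toy_maps(gm)]).transform_one(toy_maps(gm))
    c = DTLExtractor(seed=6).fit([toy_maps(gm)]).transform_one(toy_maps(gm))
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


def test_dtl_weight_file_loading_and_validation(tmp_path):
    rng = np.random.default_rng(9)
    gm = rng.random((40, 40, 40)) * 0.9
    cin_list = (1, 8, 16, 32, 64)
    couts = (8, 16, 32, 64, 64)
    arrays = {}
    for i, (cin, cout) in enumerate(zip(cin_list, couts)):
        arrays[f"W{i}"] = rng.normal(size=(2, 2, 2, cin, cout))
        arrays[f"b{i}"] = rng.normal(size=(cout,))
    good = tmp_path / "weights.npz"
    np.savez(good, **arrays)
    ext = DTLExtractor(weights_source="file", weights_file=good).fit([toy_maps(gm)])
    assert ext.transform_one(toy_maps(gm)).shape == (7680,)

    arrays["W2"] = rng.normal(size=(3, 3, 3, 16, 32))  # wrong kernel shape
    bad = tmp_path / "bad.npz"
    np.savez(bad, **arrays)
    with pytest.raises(FeatureError, match="incompatible"):
        DTLExtractor(weights_source="file", weights_file=bad).fit([toy_maps(gm)])


def test_center_fit_crops_and_pads():
    vol = np.arange(4 * 6 * 4).reshape(4, 6, 4).astype(float)
    out = center_fit(vol, (2, 8, 4))
    assert out.shape == (2, 8, 4)
    np.testing.assert_array_equal(out[:, 1:7, :], vol[1:3, :, :])
    assert out[:, 0, :].sum() == 0 and out[:, 7, :].sum() == 0


# --------------------------------------------------------------------------
# cohort-level assembly
# --------------------------------------------------------------------------


def test_extractors_preserve_subject_order():
    rng = np.random.default_rng(10)
    maps = [toy_maps(rng.random((32, 32, 16)) * 0.8) for _ in range(3)]
    ids = ["s1", "s2", "s3"]
    grid = make_patch_grid((32, 32, 16), (32, 32, 16), 16)
    labels = np.ones((32, 32, 16), dtype=np.int32)
    parc = Parcellation(labels=labels, n_regions=1)
    fms = [
        extract_features(maps, ids, VORExtractor(parc)),
        extract_features(maps, ids, PBMExtractor(grid)),
        extract_features(maps, ids, LEPExtractor(grid)),
        extract_features(maps, ids, DTLExtractor(seed=0)),
    ]
    for fm in fms:
        assert fm.subject_ids == ids
    assert [fm.method for fm in fms] == ["VOR", "PBM", "LEP", "DTL"]


def test_feature_matrix_csv_roundtrip(tmp_path):
    rng = np.random.default_rng(11)
    from brainmorph import FeatureMatrix

    fm = FeatureMatrix(rng.random((3, 5)), ["a", "b", "c"], "VOR")
    path = tmp_path / "features.csv"
    fm.to_csv(path)
    back = FeatureMatrix.from_csv(path)
    assert back.method == "VOR"
    assert back.subject_ids == fm.subject_ids
    np.testing.assert_allclose(back.values, fm.values, rtol=1e-9)
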