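"""Static radiomic feature tests: quantization, shape, first-order,
texture families, and the 111-feature vector contract."""

import numpy as np
import pytest
from scipy import stats as sps

import radiotme as rt
from radiotme.catalog import STATIC_FEATURES
from radiotme.static_features import rescale_quantize, shape_features

from conftest import make_study


def test_quantize_bin_count_and_formula(rng):
    vol = rng.uniform(0, 1000, size=(6, 6, 6))
    mask = rng.random((6, 6, 6)) < 0.7
    mask[3, 3, 3] = True
    roi = rescale_quantize(vol, mask, bits=8, bin_width=25.0)
    assert roi.n_levels <= int(np.ceil(256 / 25))
    # brute-force per-voxel recomputation
    vals = vol[mask]
    rescaled = (vals - vals.min()) / (vals.max() - vals.min()) * 255.0
    want = np.floor(rescaled / 25.0).astype(int) + 1
    np.testing.assert_array_equal(roi.levels, want)


def test_quantize_constant_roi_single_level():
    vol = np.full((4, 4, 4), 7.0)
    mask = np.ones((4, 4, 4), dtype=bool)
    roi = rescale_quantize(vol, mask)
    assert roi.n_levels == 1
    assert set(roi.levels.tolist()) == {1}


def test_quantize_rejects_bad_binwidth():
    with pytest.raises(ValueError):
        rescale_quantize(np.ones((2, 2, 2)), np.ones((2, 2, 2), bool), bin_width=0)


def test_shape_single_voxel():
    mask = np.zeros((3, 3, 3), dtype=bool)
    mask[1, 1, 1] = True
    feats = shape_features(mask, (1.0, 1.0, 1.0))
    assert feats["shape_voxel_volume"] == pytest.approx(1.0)
    assert feats["shape_major_axis_length"] == 0.0
    assert feats["shape_max_3d_diameter"] == 0.0


def test_shape_digital_ball_sphericity():
    r = 10
    n = 2 * r + 3
    zz, yy, xx = np.ogrid[:n, :n, :n]
    c = n // 2
    mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r ** 2
    feats = shape_features(mask, (1.0, 1.0, 1.0))
    assert 0.95 <= feats["shape_sphericity"] <= 1.0
    assert feats["shape_elongation"] == pytest.approx(1.0, abs=0.02)
    assert feats["shape_voxel_volume"] == pytest.approx(4 / 3 * np.pi * r ** 3, rel=0.05)


def test_shape_prolate_ellipsoid_axis_ratios():
    # semi-axes (10, 4, 4) mm: elongation and flatness ~ 4/10
    n = 31
    zz, yy, xx = np.ogrid[:n, :n, :n]
    c = n // 2
    mask = ((xx - c) / 10.0) ** 2 + ((yy - c) / 4.0) ** 2 + ((zz - c) / 4.0) ** 2 <= 1
    feats = shape_features(mask, (1.0, 1.0, 1.0))
    assert feats["shape_elongation"] == pytest.approx(0.4, abs=0.05)
    assert feats["shape_flatness"] == pytest.approx(0.4, abs=0.05)
    assert feats["shape_max_3d_diameter"] == pytest.approx(20.0, abs=1.5)


def test_first_order_constant_roi():
    study = make_study({"a": (0.0, 0.5, 0.5, 0.5)})
    feats = rt.first_order_features(study)
    c = 150.0  # reference phase intensity
    assert feats["fo_mean"] == feats["fo_median"] == feats["fo_min"] == feats["fo_max"] == c
    assert feats["fo_std"] == 0.0
    assert feats["fo_entropy"] == 0.0
    assert feats["fo_uniformity"] == 1.0
    assert feats["fo_skewness"] == 0.0
    assert feats["fo_mean_pre"] == pytest.approx(100.0)
    assert feats["fo_mean_post1"] == pytest.approx(150.0)


def test_first_order_against_direct_formulas(rng):
    mask = rng.random((5, 5, 5)) < 0.7
    mask[2, 2, 2] = True
    phases = np.full((4, 5, 5, 5), 100.0)
    phases[1][mask] = rng.uniform(50, 400, size=int(mask.sum()))
    study = rt.DceStudy(phases=phases, spacing=(1.5, 0.8, 0.8),
                        times=(0, 1, 2, 3), mask=mask)
    feats = rt.first_order_features(study)
    v = phases[1][mask]
    assert feats["fo_mean"] == pytest.approx(v.mean(), rel=1e-12)
    assert feats["fo_p10"] == pytest.approx(np.percentile(v, 10), rel=1e-12)
    assert feats["fo_iqr"] == pytest.approx(
        np.percentile(v, 75) - np.percentile(v, 25), rel=1e-12)
    assert feats["fo_mad"] == pytest.approx(np.abs(v - v.mean()).mean(), rel=1e-12)
    assert feats["fo_rms"] == pytest.approx(np.sqrt((v ** 2).mean()), rel=1e-12)
    assert feats["fo_energy"] == pytest.approx((v ** 2).sum(), rel=1e-12)
    assert feats["fo_total_energy"] == pytest.approx(
        (v ** 2).sum() * 1.5 * 0.8 * 0.8, rel=1e-12)
    assert feats["fo_skewness"] == pytest.approx(sps.skew(v), rel=1e-9)
    assert feats["fo_kurtosis"] == pytest.approx(
        sps.kurtosis(v, fisher=False), rel=1e-9)


def test_static_vector_contract_and_determinism():
    cfg = rt.CohortConfig(n_lesions=2, seed=4)
    study, _ = rt.gen_lesion_study(cfg, 0)
    v1 = rt.static_feature_vector(study)
    v2 = rt.static_feature_vector(study)
    assert list(v1) == STATIC_FEATURES
    assert len(v1) == 111
    assert all(np.isfinite(list(v1.values())))
    assert v1 == v2


def test_shape_invariant_to_intensity_scaling():
    cfg = rt.CohortConfig(n_lesions=2, seed=4)
    study, _ = rt.gen_lesion_study(cfg, 0)
    s1 = rt.shape_features(study.mask, study.spacing)
    study2 = rt.DceStudy(phases=study.phases * 3.7, spacing=study.spacing,
                         times=study.times, mask=study.mask)
    v2 = rt.static_feature_vector(study2)
    for k, v in s1.items():
        assert v2[k] == pytest.approx(v, rel=1e-12)


def test_direction_averaged_families_rotation_invariant(rng):
    """90-degree rotation about an axis leaves direction-pooled GLCM and
    GLRLM descriptors unchanged on an isotropic grid."""
    vol = rng.uniform(0, 100, size=(6, 6, 6))
    mask = rng.random((6, 6, 6)) < 0.75
    mask[3, 3, 3] = True
    roi = rescale_quantize(vol, mask, bin_width=40.0)
    rot_vol = np.rot90(vol, k=1, axes=(1, 2))
    rot_mask = np.rot90(mask, k=1, axes=(1, 2))
    roi_r = rescale_quantize(rot_vol, rot_mask, bin_width=40.0)
    for fam in ("GLCM", "GLRLM"):
        a = rt.texture_matrix_features(roi, fam)
        b = rt.texture_matrix_features(roi_r, fam)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9), k


def test_texture_probability_matrices_counts():
    cfg = rt.CohortConfig(n_lesions=2, seed=6)
    study, _ = rt.gen_lesion_study(cfg, 1)
    roi = rescale_quantize(study.phases[1], study.mask)
    from radiotme import texture as tx
    P = tx.glcm_matrix(roi.label_volume, roi.mask, roi.n_levels)
    assert P.sum() == pytest.approx(1.0, abs=1e-12)
    R = tx.glrlm_matrix(roi.label_volume, roi.mask, roi.n_levels)
    assert np.all(R >= 0) and np.allclose(R, np.round(R))
    Z = tx.glszm_matrix(roi.label_volume, roi.mask, roi.n_levels)
    # zones partition the mask: sizes weighted by counts sum to mask size
    sizes = np.arange(1, Z.shape[1] + 1)
    assert (Z * sizes).sum() == pytest.approx(study.n_voxels)
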