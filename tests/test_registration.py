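"""Feature-based registration: preprocessing, SIFT, matching, RANSAC, warping."""

import numpy as np
import pytest

from spatiomux import RegistrationError
from spatiomux.registration import (
    RegistrationResult,
    apply_transform_image,
    detect_and_describe,
    estimate_transform,
    match_descriptors_ratio,
    preprocess_for_features,
    register_pair,
    transform_points,
)
from spatiomux.synthetic import generate_registration_pair

CORNERS_512 = np.array([[0, 0], [512, 0], [0, 512], [512, 512]], dtype=float)


def _corner_error(result_matrix, planted, corners=CORNERS_512):
    a = transform_points(corners, result_matrix)
    b = transform_points(corners, planted)
    return float(np.linalg.norm(a - b, axis=1).mean())


@pytest.fixture(scope="module")
def planted_pair():
    return generate_registration_pair(
        seed=3, rotation_deg=10, scale=1.1, shift_px=(15, -10), image_px=512
    )


class TestPreprocess:
    def test_downscale_factor(self):
        big = np.random.default_rng(0).integers(0, 255, (800, 800)).astype(np.uint8)
        out, factor = preprocess_for_features(big, cap=400)
        assert factor == 2
        assert max(out.shape) <= 400

    def test_no_downscale_when_within_cap(self):
        img = np.random.default_rng(0).integers(0, 255, (100, 120)).astype(np.uint8)
        out, factor = preprocess_for_features(img, cap=4096)
        assert factor == 1 and out.shape == (100, 120)

    def test_rgb_converted_and_inverted(self):
        rgb = np.zeros((50, 50, 3), dtype=np.uint8)
        rgb[10:20, 10:20] = 200
        plain, _ = preprocess_for_features(rgb)
        inverted, _ = preprocess_for_features(rgb, invert=True)
        assert plain.ndim == 2
        assert plain[15, 15] > plain[0, 0]
        assert inverted[15, 15] < inverted[0, 0]

    def test_constant_image_yields_no_keypoints(self):
        out, _ = preprocess_for_features(np.full((64, 64), 7, dtype=np.uint8))
        kp, desc = detect_and_describe(out)
        assert len(kp) == 0 and len(desc) == 0


class TestDetect:
    def test_synthetic_nuclei_image_is_feature_rich(self):
        fixed, _, _ = generate_registration_pair(seed=0, image_px=512)
        img8, _ = preprocess_for_features(fixed)
        kp, desc = detect_and_describe(img8)
        assert len(kp) >= 50
        assert desc.shape[1] == 128

    def test_rotation_invariance_of_descriptors(self):
        fixed, _, _ = generate_registration_pair(seed=0, image_px=256)
        img8, _ = preprocess_for_features(fixed)
        rot = np.rot90(img8).copy()
        _, d0 = detect_and_describe(img8)
        _, d1 = detect_and_describe(rot)
        matches = match_descriptors_ratio(d0, d1)
        assert len(matches) >= 0.3 * min(len(d0), len(d1))


class TestMatching:
    def test_identical_sets_match_one_to_one(self):
        rng = np.random.default_rng(2)
        desc = rng.random((40, 128))
        matches = match_descriptors_ratio(desc, desc, ratio=0.9)
        assert len(matches) == 40
        assert np.array_equal(matches[:, 0], matches[:, 1])

    def test_disjoint_random_descriptors_barely_match(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((100, 128)), rng.random((100, 128))
        matches = match_descriptors_ratio(a, b, ratio=0.75)
        assert len(matches) <= 5  # null simulation: ~0 survivors

    def test_ratio_monotonicity(self):
        rng = np.random.default_rng(3)
        a = rng.random((80, 128))
        b = a + rng.normal(0, 0.05, a.shape)
        loose = match_descriptors_ratio(a, b, ratio=1.0)
        tight = match_descriptors_ratio(a, b, ratio=0.75)
        assert len(loose) >= len(tight)

    def test_single_descriptor_cannot_pass_ratio_test(self):
        one = np.random.default_rng(0).random((1, 128))
        assert len(match_descriptors_ratio(one, one)) == 0


class TestEstimate:
    def test_exact_fit_recovers_planted_affine(self):
        rng = np.random.default_rng(4)
        planted = np.array([[1.05, 0.1, 12.0], [-0.08, 0.97, -5.0], [0, 0, 1.0]])
        src = rng.uniform(0, 512, (50, 2))
        dst = transform_points(src, planted)
        res = estimate_transform(src, dst, kind="affine", seed=0)
        assert res.n_inliers == 50
        assert _corner_error(res.transform, planted) < 1e-3

    def test_outliers_rejected(self):
        rng = np.random.default_rng(2)
        planted = np.array([[0.95, -0.2, 30.0], [0.2, 0.95, -20.0], [0, 0, 1.0]])
        src = rng.uniform(0, 512, (100, 2))
        dst = transform_points(src, planted)
        n_out = 30
        dst[:n_out] = rng.uniform(0, 512, (n_out, 2))  # 30% corrupted
        res = estimate_transform(src, dst, kind="affine", ransac_threshold_px=2.0, seed=2)
        assert res.n_inliers <= 100 - n_out + 2  # outliers excluded (chance grazes allowed)
        assert _corner_error(res.transform, planted) < 1.0

    def test_too_few_matches_raise_with_counts(self):
        with pytest.raises(RegistrationError) as err:
            estimate_transform(np.zeros((2, 2)), np.zeros((2, 2)), kind="affine")
        assert err.value.counts["n_matches"] == 2
        with pytest.raises(RegistrationError):
            estimate_transform(np.zeros((3, 2)), np.zeros((3, 2)), kind="perspective")

    def test_inlier_count_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        planted = np.array([[1.0, 0.0, 5.0], [0.0, 1.0, -3.0], [0, 0, 1.0]])
        src = rng.uniform(0, 512, (200, 2))
        dst = transform_points(src, planted) + rng.normal(0, 1.5, (200, 2))
        counts = [
            estimate_transform(src, dst, ransac_threshold_px=t, seed=8).n_inliers
            for t in (8.0, 4.0, 2.0, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestRegisterPair:
    def test_self_registration_is_near_identity(self):
        fixed, _, _ = generate_registration_pair(seed=0, image_px=512)
        res = register_pair(fixed, fixed)
        assert _corner_error(res.transform, np.eye(3)) < 0.5
        assert not res.flagged

    def test_planted_transform_recovered(self, planted_pair):
        fixed, moving, planted = planted_pair
        res = register_pair(fixed, moving, seed=3)
        assert _corner_error(res.transform, planted) < 2.0
        assert res.n_inliers >= 10
        assert res.mean_reprojection_error < 5.0

    def test_unrelated_images_fail_or_flag(self):
        fixed, _, _ = generate_registration_pair(seed=4, image_px=512)
        other, _, _ = generate_registration_pair(seed=104, image_px=512)
        try:
            res = register_pair(fixed, other, seed=4)
        except RegistrationError as err:
            assert err.stage in ("detect", "match", "estimate")
        else:
            assert res.flagged or res.inlier_fraction < 0.2 or res.n_inliers < 10

    def test_qc_metrics_populated(self, planted_pair):
        fixed, moving, _ = planted_pair
        res = register_pair(fixed, moving, seed=3)
        qc = res.qc_dict()
        assert qc["n_keypoints_fixed"] > 0 and qc["n_keypoints_moving"] > 0
        assert qc["n_inliers"] <= qc["n_matches"]
        assert qc["mean_reprojection_error"] >= 0
        assert qc["downscale_factor"] == 1.0


class TestApplyTransform:
    def test_identity_leaves_image_unchanged(self):
        img = np.random.default_rng(0).integers(0, 255, (64, 64)).astype(np.uint8)
        out = apply_transform_image(img, np.eye(3), (64, 64))
        np.testing.assert_array_equal(out, img)

    def test_translation_zero_fills_vacated_columns(self):
        img = np.full((32, 32), 100, dtype=np.uint8)
        shift = np.array([[1, 0, 10], [0, 1, 0], [0, 0, 1]], dtype=float)
        out = apply_transform_image(img, shift, (32, 32))
        assert np.all(out[:, :10] == 0)
        assert np.all(out[:, 10:] == 100)

    def test_warp_then_inverse_correlates_with_original(self, planted_pair):
        fixed, _, planted = planted_pair
        arr = fixed.pixels.astype(float)
        fwd = apply_transform_image(arr, planted, arr.shape)
        back = apply_transform_image(fwd, np.linalg.inv(planted), arr.shape)
        interior = (slice(64, -64), slice(64, -64))
        a, b = arr[interior].ravel(), back[interior].ravel()
        ncc = np.corrcoef(a, b)[0, 1]
        assert ncc >= 0.98

    def test_singular_transform_rejected(self):
        bad = np.zeros((3, 3))
        with pytest.raises(ValueError):
            apply_transform_image(np.zeros((8, 8)), bad, (8, 8))


class TestTransformPoints:
    def test_identity_and_translation(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        np.testing.assert_allclose(transform_points(pts, np.eye(3)), pts)
        t = np.array([[1, 0, 5], [0, 1, 7], [0, 0, 1]], dtype=float)
        np.testing.assert_allclose(transform_points([[0, 0]], t), [[5, 7]])

    def test_matches_manual_matrix_multiplication(self):
        rng = np.random.default_rng(9)
        m = np.array([[1.2, -0.3, 8.0], [0.4, 0.9, -2.0], [0, 0, 1.0]])
        pts = rng.uniform(-100, 100, (200, 2))
        manual = np.array([(m @ np.array([x, y, 1.0]))[:2] for x, y in pts])
        np.testing.assert_allclose(transform_points(pts, m), manual, atol=1e-9)

    def test_round_trip_through_inverse(self):
        rng = np.random.default_rng(10)
        m = np.array([[1.1, 0.2, 3.0], [-0.1, 0.95, 1.0], [1e-4, -2e-4, 1.0]])
        pts = rng.uniform(0, 200, (50, 2))
        back = transform_points(transform_points(pts, m), np.linalg.inv(m))
        np.testing.assert_allclose(back, pts, atol=1e-6)

    def test_vanishing_homogeneous_weight_flagged_nan(self):
        m = np.array([[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 1.0]])  # w = 1 - x
        out = transform_points([[1.0, 0.0], [0.5, 0.5]], m)
        assert np.isnan(out[0]).all()
        assert np.isfinite(out[1]).all()


def test_registration_result_invariants():
    with pytest.raises(ValueError):
        RegistrationResult(np.eye(3), "affine", n_matches=3, n_inliers=5)
    bad = np.eye(3)
    bad[2, 0] = 0.5
    with pytest.raises(ValueError):
        RegistrationResult(bad, "affine")
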