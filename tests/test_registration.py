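"""Baseline aligners, stack propagation and transform re-application."""

import numpy as np
import pytest
from skimage.transform import warp

from histobench.exceptions import DegenerateInputError, MatchFailureError
from histobench.registration import (
    alignment_from_csv,
    alignment_from_json,
    alignment_to_csv,
    alignment_to_json,
    apply_alignment,
    detect_failure,
    fit_affine_ls,
    ls_aligner,
    opt_aligner,
    register_pair_features,
    register_pair_opt,
    register_stack,
)
from histobench.stack_io import SectionStack, decode_pairwise_landmarks, to_gray
from histobench.transform import PlanarTransform, StackAlignment

CORNERS = np.array([[0.0, 0.0], [191.0, 0.0], [0.0, 191.0], [191.0, 191.0]])


def _warped(image, tform, cval=245.0, order=3):
    """moving(y) = fixed(T(y)): content displaced by T^-1."""
    out = warp(image.astype(float), tform.as_skimage(), order=order,
               preserve_range=True, cval=cval)
    return out.astype(image.dtype) if image.dtype == np.uint8 else out


class TestFitAffineLs:
    def test_exact_affine_recovered_from_three_points(self, rng):
        true = PlanarTransform(np.array([[1.1, 0.2, 5.0], [-0.1, 0.95, -3.0]]))
        src = rng.uniform(0, 100, (3, 2))
        est = fit_affine_ls(src, true.apply(src))
        assert np.abs(np.linalg.norm(
            est.apply(src) - true.apply(src), axis=1)).max() < 1e-9

    def test_identity_when_src_equals_dst(self, rng):
        pts = rng.uniform(0, 50, (4, 2))
        est = fit_affine_ls(pts, pts)
        assert est.almost_equals(PlanarTransform.identity(), atol=1e-10)

    def test_rigid_procrustes_recovers_rotation(self, rng):
        true = PlanarTransform.from_params(4.0, -2.0, rotation_deg=25.0,
                                           model="rigid")
        src = rng.uniform(0, 100, (5, 2))
        est = fit_affine_ls(src, true.apply(src), model="rigid")
        assert est.model == "rigid"
        np.testing.assert_allclose(est.matrix, true.matrix, atol=1e-9)

    def test_rigid_never_reflects(self):
        src = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        dst = src * np.array([1.0, -1.0])  # a reflection
        est = fit_affine_ls(src, dst, model="rigid")
        assert np.linalg.det(est.linear) == pytest.approx(1.0)

    def test_collinear_points_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(DegenerateInputError, match="collinear"):
            fit_affine_ls(src, src)

    def test_noisy_estimates_unbiased_over_monte_carlo(self):
        """Mean recovered matrix over 100 noisy fits is within 3 standard
        errors of the generating transform (sigma = 1 px, 50 points)."""
        true = PlanarTransform(np.array([[1.05, 0.1, 8.0], [-0.08, 0.98, -5.0]]))
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 200, (50, 2))
        mats = []
        for _ in range(100):
            noisy = true.apply(src) + rng.normal(0, 1.0, (50, 2))
            mats.append(fit_affine_ls(src, noisy).matrix)
        mats = np.array(mats)
        se = mats.std(axis=0, ddof=1) / 10.0  # sqrt(100)
        assert (np.abs(mats.mean(axis=0) - true.matrix) < 3 * se + 1e-12).all()


class TestRegisterPairOpt:
    def test_self_registration_is_identity(self, small_phantom):
        img = to_gray(small_phantom.tissue[3])
        est = register_pair_opt(img, img, model="rigid")
        disp = np.linalg.norm(est.apply(CORNERS) - CORNERS, axis=1)
        assert disp.max() < 0.1

    def test_translation_recovered_within_half_pixel(self, small_phantom):
        img = to_gray(small_phantom.tissue[3])
        true = PlanarTransform.from_params(12.0, -7.0, model="rigid")
        mov = _warped(img, true)
        est = register_pair_opt(img, mov, model="translation")
        np.testing.assert_allclose(est.translation, [12.0, -7.0], atol=0.5)

    def test_rotation_recovered_within_fifth_of_degree(self, small_phantom):
        img = to_gray(small_phantom.tissue[3])
        true = PlanarTransform.from_params(rotation_deg=5.0,
                                           center=(95.5, 95.5), model="rigid")
        est = register_pair_opt(img, _warped(img, true), model="rigid")
        angle = np.rad2deg(np.arctan2(est.matrix[1, 0], est.matrix[0, 0]))
        assert angle == pytest.approx(5.0, abs=0.2)

    def test_deterministic_given_inputs(self, small_phantom):
        img = to_gray(small_phantom.tissue[2])
        mov = to_gray(small_phantom.tissue[3])
        a = register_pair_opt(img, mov, model="rigid")
        b = register_pair_opt(img, mov, model="rigid")
        np.testing.assert_array_equal(a.matrix, b.matrix)


class TestRegisterPairFeatures:
    def test_known_transform_recovered(self, small_phantom):
        img = small_phantom.tissue[2]
        true = PlanarTransform.from_params(20.0, 5.0, rotation_deg=10.0,
                                           center=(95.5, 95.5), model="rigid")
        mov = _warped(img, true, order=1)
        est = register_pair_features(img, mov, seed=1)
        pts = small_phantom.ground_truth.landmarks_true.df.query(
            "section == 2")[["x", "y"]].to_numpy()
        # est maps moving-frame points onto the fixed frame
        err = np.linalg.norm(est.apply(true.inverse().apply(pts)) - pts, axis=1)
        assert err.mean() < 0.5
        assert est.n_inliers >= 6

    def test_self_match_is_identity_within_threshold(self, small_phantom):
        img = small_phantom.tissue[2]
        est = register_pair_features(img, img, seed=0, ransac_threshold_px=3.0)
        disp = np.linalg.norm(est.apply(CORNERS) - CORNERS, axis=1)
        assert disp.max() < 3.0

    def test_featureless_images_raise_match_failure(self):
        flat = np.full((128, 128, 3), 200, np.uint8)
        with pytest.raises(MatchFailureError):
            register_pair_features(flat, flat)


class TestRegisterStack:
    def test_identical_sections_give_identity(self, small_phantom):
        img = small_phantom.tissue[0]
        stack = SectionStack([img.copy() for _ in range(3)])
        al = register_stack(stack, opt_aligner(model="translation"),
                            reference_index=1)
        for tf in al.transforms:
            disp = np.linalg.norm(tf.apply(CORNERS) - CORNERS, axis=1)
            assert disp.max() < 0.2

    def test_ls_on_true_landmarks_recovers_ground_truth(self, small_phantom):
        d = small_phantom
        al = register_stack(d.tissue, ls_aligner(d.ground_truth.landmarks_true),
                            reference_index=2)
        g2 = d.ground_truth.transforms[2]
        for i, tf in enumerate(al.transforms):
            true_global = g2 @ d.ground_truth.transforms[i].inverse()
            err = np.linalg.norm(
                tf.apply(CORNERS) - true_global.apply(CORNERS), axis=1)
            assert err.max() < 0.5

    def test_composition_consistency_along_chain(self, small_phantom):
        d = small_phantom
        method = ls_aligner(d.ground_truth.landmarks_true)
        al = register_stack(d.tissue, method, reference_index=2)
        for i in range(3, d.tissue.n_sections):
            pair = method(None, None, fixed_index=i - 1, moving_index=i)
            np.testing.assert_allclose(
                al.transforms[i].matrix, (al.transforms[i - 1] @ pair).matrix,
                atol=1e-12)

    def test_reversed_stack_gives_inverse_geometry(self, small_phantom):
        d = small_phantom
        n = d.tissue.n_sections
        al_fwd = register_stack(d.tissue, ls_aligner(d.ground_truth.landmarks_true),
                                reference_index=0)
        # reverse the section order (and the landmark table accordingly)
        rev_df = d.ground_truth.landmarks_true.df.copy()
        rev_df["section"] = n - 1 - rev_df["section"]
        rev_df["pair"] = n - 2 - rev_df["pair"]
        from histobench.stack_io import LandmarkSet

        rev_stack = SectionStack(d.tissue.images[::-1],
                                 pixel_size=d.tissue.pixel_size)
        al_rev = register_stack(rev_stack, ls_aligner(LandmarkSet(rev_df)),
                                reference_index=n - 1)
        for i in range(n):
            np.testing.assert_allclose(
                al_rev.transforms[n - 1 - i].apply(CORNERS),
                al_fwd.transforms[i].apply(CORNERS), atol=1e-6)

    def test_pair_failure_falls_back_to_identity(self, small_phantom):
        calls = []

        def flaky(fixed, moving, *, fixed_index, moving_index):
            calls.append((fixed_index, moving_index))
            if moving_index == 2:
                raise MatchFailureError("no matches")
            return PlanarTransform.from_params(1.0, 0.0, model="rigid")

        with pytest.warns(UserWarning, match="identity fallback"):
            al = register_stack(small_phantom.tissue, flaky, reference_index=0)
        assert al.pair_failures == [1]


class TestApplyAlignment:
    def test_identity_alignment_is_lossless(self, small_phantom):
        stack = small_phantom.tissue
        al = StackAlignment([PlanarTransform.identity()] * stack.n_sections, 0)
        out = apply_alignment(stack, al)
        assert out.shapes == stack.shapes
        for a, b in zip(stack.images, out.images):
            np.testing.assert_array_equal(a, b)

    def test_pure_translation_nearest_is_permutation(self):
        rng = np.random.default_rng(3)
        img = rng.integers(1, 255, (32, 32)).astype(np.uint8)
        ref = rng.integers(1, 255, (32, 32)).astype(np.uint8)
        stack = SectionStack([ref, img])
        shift = PlanarTransform.from_params(5.0, 3.0, model="rigid")
        al = StackAlignment([PlanarTransform.identity(), shift], 0)
        out = apply_alignment(stack, al, interpolation="nearest")
        # shifted section: every value moved intact, zero fill elsewhere
        np.testing.assert_array_equal(out[1][3:35, 5:37], img)
        assert out[1][:3, :].sum() == 0 and out[1][:, :5].sum() == 0
        np.testing.assert_array_equal(out[0][0:32, 0:32], ref)

    def test_warp_then_decode_equals_direct_coordinates(self, small_phantom):
        """The core re-application contract: transforming landmark images and
        decoding agrees with mapping the coordinates directly."""
        d = small_phantom
        al = register_stack(d.tissue, ls_aligner(d.landmarks.for_observer(1)),
                            reference_index=3)
        warped = [apply_alignment(s, al) for s in d.landmark_stacks(1)]
        decoded = decode_pairwise_landmarks(warped[0], warped[1], d.colormap)
        _, offset = al.canvas(d.tissue.shapes)
        shift = PlanarTransform(np.column_stack([np.eye(2), -offset]))
        direct = d.landmarks.for_observer(1).transformed(
            [shift @ t for t in al.transforms])
        m = decoded.df.merge(direct.df, on=["section", "point_id", "pair"],
                             suffixes=("_img", "_dir"))
        err = np.hypot(m.x_img - m.x_dir, m.y_img - m.y_dir)
        assert len(m) == len(direct.df)
        assert err.max() <= 0.5


class TestDetectFailure:
    def _alignment(self, scale):
        return StackAlignment(
            [PlanarTransform.identity(),
             PlanarTransform(np.array([[scale, 0.0, 0.0], [0.0, 1.0, 0.0]]))], 0)

    def test_runaway_canvas_is_failure(self):
        assert detect_failure(self._alignment(5.2), (100, 100))

    def test_identity_is_not_failure(self):
        al = StackAlignment([PlanarTransform.identity()] * 3, 0)
        assert not detect_failure(al, (100, 100))

    def test_exactly_fivefold_is_not_failure(self):
        # strictly "over fivefold": canvas width exactly 5x input passes
        tr = PlanarTransform(np.array([[1.0, 0.0, 399.0], [0.0, 1.0, 0.0]]))
        al = StackAlignment([PlanarTransform.identity(), tr], 0)
        # canvas = [0, 399 + 99] -> width 499 < 500
        assert not detect_failure(al, (100, 100))
        tr2 = PlanarTransform(np.array([[1.0, 0.0, 401.0], [0.0, 1.0, 0.0]]))
        al2 = StackAlignment([PlanarTransform.identity(), tr2], 0)
        assert detect_failure(al2, (100, 100))


class TestSerialization:
    def test_csv_round_trip(self, tmp_path, small_phantom):
        al = register_stack(
            small_phantom.tissue,
            ls_aligner(small_phantom.ground_truth.landmarks_true),
            reference_index=2)
        path = tmp_path / "transforms.csv"
        alignment_to_csv(al, path)
        back = alignment_from_csv(path)
        assert back.reference_index == 2
        for a, b in zip(al.transforms, back.transforms):
            np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)

    def test_json_round_trip(self, tmp_path):
        al = StackAlignment(
            [PlanarTransform.identity(),
             PlanarTransform.from_params(3.0, -2.0, rotation_deg=4.0)], 0)
        path = tmp_path / "transforms.json"
        alignment_to_json(al, path)
        back = alignment_from_json(path)
        for a, b in zip(al.transforms, back.transforms):
            np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)
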