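"""Slice matching, orientation ranking, affine and TPS registration, masks."""

import warnings

import nibabel as nib
import numpy as np
import pytest
from scipy import ndimage

from ihcmap import phantoms, register as R


CORNERS_96 = np.array([[0, 0], [0, 95], [95, 0], [95, 95]], float)


class TestNiftiPlumbing:
    def test_single_slice_dims(self):
        img = R.image_to_slice_nifti(np.zeros((100, 80)) + 1.0)
        assert img.shape == (100, 80, 1)

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 1, (32, 40)).astype(np.float32)
        img = R.image_to_slice_nifti(data, (0.07, 0.07, 1.0))
        nib.save(img, str(tmp_path / "x.nii.gz"))
        again = np.asarray(nib.load(str(tmp_path / "x.nii.gz")).dataobj)
        assert np.array_equal(again[:, :, 0], data)

    def test_rgb_converted_by_rec601_luma(self):
        rgb = np.zeros((2, 2, 3), np.uint8)
        rgb[0, 0] = (255, 0, 0)
        img = R.image_to_slice_nifti(rgb)
        assert abs(float(img.get_fdata()[0, 0, 0]) - 0.299 * 255) <= 1.0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            R.image_to_slice_nifti(np.zeros((0, 0)))


class TestPreprocessForRegistration:
    def test_output_range_unit_interval(self, histology_template):
        out = R.preprocess_for_registration(histology_template)
        assert out.min() == 0.0 and out.max() <= 1.0 and out.max() > 0.9

    def test_constant_image_unchanged_with_warning(self):
        img = np.full((16, 16), 3.3)
        with pytest.warns(UserWarning, match="constant"):
            out = R.preprocess_for_registration(img)
        assert np.array_equal(out, img)

    def test_near_idempotent_on_equalized_input(self):
        from skimage import exposure

        rng = np.random.default_rng(0)
        smooth = ndimage.gaussian_filter(rng.standard_normal((128, 128)), 4)
        eq = exposure.equalize_hist(smooth)
        first = R.preprocess_for_registration(eq)
        second = R.preprocess_for_registration(first)
        assert (np.abs(second - first) > 0.01).mean() <= 0.01


class TestPlaneAndSlice:
    def test_axial_slab_selects_axis(self):
        vol = np.zeros((10, 12, 14))
        vol[4] = 1.0
        assert R.find_plane(vol) == 0

    def test_matches_exhaustive_count_oracle(self, mri_phantom):
        vol = mri_phantom.volume
        best = [
            max(np.count_nonzero(np.take(vol, i, axis=ax)) for i in range(vol.shape[ax]))
            for ax in range(3)
        ]
        assert R.find_plane(vol) == int(np.argmax(best))

    def test_exact_axis_tie_goes_to_axis_zero(self):
        vol = np.zeros((4, 4, 4))
        vol[1, 1, 1] = 1.0  # same single-voxel count on all axes
        assert R.find_plane(vol) == 0

    def test_all_zero_volume_is_error(self):
        with pytest.raises(ValueError):
            R.find_plane(np.zeros((3, 3, 3)))

    def test_phantom_slice_recovered_with_default_nmi(self, mri_phantom, histology_template):
        hist = R.preprocess_for_registration(histology_template)
        match = R.find_best_slice(mri_phantom.volume, hist)  # default metric
        assert match.metric == "nmi"
        assert match.plane_axis == mri_phantom.truth_plane
        assert match.slice_index == mri_phantom.truth_slice
        assert set(match.scores.columns) == {"nmi", "ncc", "ssim", "feature"}

    def test_identical_slices_pick_lowest_index_with_warning(self, histology_template):
        sl = histology_template
        vol = np.stack([sl] * 4, axis=0)
        hist = R.preprocess_for_registration(histology_template)
        with pytest.warns(UserWarning, match="identically"):
            match = R.find_best_slice(vol, hist, metric="ncc", all_metrics=False)
        assert match.slice_index == 0


class TestScoreSlice:
    def test_self_similarity_maxima(self, histology_template):
        t = histology_template
        assert R.score_slice(t, t, "ncc") == pytest.approx(1.0)
        assert R.score_slice(t, t, "ssim") == pytest.approx(1.0)

    def test_ncc_antisymmetric_under_negation(self, histology_template):
        t = histology_template
        assert R.score_slice(t, -t, "ncc") == pytest.approx(-1.0)

    def test_nmi_drops_under_permutation(self, histology_template):
        t = histology_template
        rng = np.random.default_rng(0)
        perm = t.copy().ravel()
        rng.shuffle(perm)
        perm = perm.reshape(t.shape)
        assert R.score_slice(t, t, "nmi") > R.score_slice(t, perm, "nmi")

    def test_unknown_metric_rejected(self, histology_template):
        with pytest.raises(ValueError):
            R.score_slice(histology_template, histology_template, "dice")


class TestOrientations:
    def test_orientation_then_inverse_is_identity(self, histology_template):
        for op in range(R.N_ORIENTATIONS):
            out = R.apply_orientation(
                R.apply_orientation(histology_template, op), R.invert_orientation(op)
            )
            assert np.array_equal(out, histology_template)

    def test_truth_orientation_ranks_first(self, mri_phantom, histology_template):
        hist = R.preprocess_for_registration(histology_template)
        sl = np.take(mri_phantom.volume, mri_phantom.truth_slice, axis=mri_phantom.truth_plane)
        ranking = R.rank_orientations(hist, sl)
        assert ranking[0][0] == mri_phantom.truth_orientation

    def test_symmetric_pattern_has_stable_tie_order(self):
        disc = np.zeros((64, 64))
        yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        disc[(yy - 31.5) ** 2 + (xx - 31.5) ** 2 < 400] = 1.0
        r1 = R.rank_orientations(disc, disc)
        r2 = R.rank_orientations(disc, disc)
        assert [op for op, _ in r1] == [op for op, _ in r2]


class TestLinearRegister:
    def test_identity_method_returns_input(self, histology_template):
        aff, warped, report = R.linear_register(
            histology_template, histology_template, method="identity"
        )
        assert np.allclose(aff.matrix, np.hstack([np.eye(2), np.zeros((2, 1))]))
        assert np.array_equal(warped, histology_template)
        assert report["success"]

    def test_known_affine_recovered_by_ncc(self):
        tpl = phantoms.make_histology_template(seed=0, size=128)
        ctr = ((128 - 1) / 2.0,) * 2
        truth = R.Affine2D.from_params(
            rotation_deg=5, scale=(1.05, 1.05), translation=(3, -2), center=ctr
        )
        fixed = truth.warp(tpl, output_shape=tpl.shape)
        est, _, report = R.linear_register(tpl, fixed, method="ncc")
        corners = np.array([[0, 0], [0, 127], [127, 0], [127, 127]], float)
        err = np.linalg.norm(est.apply_points(corners) - truth.apply_points(corners), axis=1)
        assert err.mean() <= 0.5
        assert report["success"]

    def test_post_registration_nmi_not_worse(self, mri_phantom, histology_template):
        moving = R.preprocess_for_registration(
            R.apply_orientation(histology_template, mri_phantom.truth_orientation)
        )
        fixed = R.preprocess_for_registration(mri_phantom.truth_slice_image)
        _, _, report = R.linear_register(moving, fixed, method="nmi")
        assert report["post"]["nmi"] >= report["pre"]["nmi"] - 1e-9
        assert "overlay" in report and "difference" in report

    def test_unknown_method_rejected(self, histology_template):
        with pytest.raises(ValueError):
            R.linear_register(histology_template, histology_template, method="ssd")


class TestTPS:
    def test_affine_consistent_landmarks_give_zero_weights(self):
        aff = R.Affine2D.from_params(rotation_deg=10, scale=(1.1, 0.95),
                                     translation=(4, 2), center=(50, 50))
        tgt = np.array([[r, c] for r in range(0, 100, 12) for c in range(0, 100, 12)], float)
        src = aff.inverse().apply_points(tgt)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = R.tps_fit(np.hstack([src, tgt]), smoothing=0.0)
        assert np.abs(model.weights).max() <= 1e-6
        # and the model equals the affine on a test grid within 1e-6 px
        probe = np.array([[r, c] for r in range(5, 95, 17) for c in range(5, 95, 17)], float)
        assert np.abs(model(probe) - aff.inverse().apply_points(probe)).max() <= 1e-6

    def test_smoothing_zero_interpolates_exactly(self):
        rng = np.random.default_rng(3)
        tgt = rng.uniform(0, 100, (50, 2))
        src = tgt + 3 * np.sin(tgt / 15.0)
        model = R.tps_fit(np.hstack([src, tgt]), smoothing=0.0)
        assert np.abs(model(tgt) - src).max() <= 1e-8

    def test_two_landmarks_rejected(self):
        with pytest.raises(ValueError):
            R.tps_fit(np.array([[0, 0, 0, 0], [1, 1, 1, 1.0]]))

    def test_collinear_landmarks_rejected(self):
        pairs = np.array([[0, 0, 0, 0], [1, 1, 1, 1], [2, 2, 2, 2.0]])
        with pytest.raises(ValueError, match="collinear"):
            R.tps_fit(pairs, smoothing=0.0)

    def test_duplicate_source_points_rejected(self):
        pairs = np.array([[0, 0, 0, 0], [0, 0, 5, 5], [1, 3, 1, 3.0], [4, 1, 4, 1.0]])
        with pytest.raises(ValueError, match="duplicate"):
            R.tps_fit(pairs, smoothing=0.0)

    def test_landmark_cap_enforced(self):
        rng = np.random.default_rng(0)
        tgt = rng.uniform(0, 1000, (501, 2))
        pairs = np.hstack([tgt, tgt])
        with pytest.raises(ValueError, match="cap"):
            R.tps_fit(pairs)

    def test_few_landmarks_warn(self):
        rng = np.random.default_rng(1)
        tgt = rng.uniform(0, 50, (5, 2))
        with pytest.warns(UserWarning, match="landmark"):
            R.tps_fit(np.hstack([tgt + 0.5, tgt]), smoothing=0.0)

    def test_matches_scipy_rbf_thin_plate(self):
        from scipy.interpolate import RBFInterpolator

        rng = np.random.default_rng(4)
        tgt = rng.uniform(0, 80, (40, 2))
        src = tgt + 2 * np.cos(tgt / 11.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = R.tps_fit(np.hstack([src, tgt]), smoothing=0.0)
        probe = rng.uniform(5, 75, (30, 2))
        for dim in (0, 1):
            rbf = RBFInterpolator(tgt, src[:, dim], kernel="thin_plate_spline",
                                  degree=1, smoothing=0.0)
            assert np.abs(model(probe)[:, dim] - rbf(probe)).max() <= 1e-9


class TestTPSApply:
    def test_identity_model_returns_input(self, histology_template):
        tgt = np.array([[r, c] for r in range(0, 96, 16) for c in range(0, 96, 16)], float)
        model = R.tps_fit(np.hstack([tgt, tgt]), smoothing=0.0)
        warped, field = R.tps_apply(model, histology_template)
        assert np.allclose(warped, histology_template, atol=1e-9)
        assert field.shape == histology_template.shape + (2,)

    def test_truth_warp_field_reproduced_from_landmarks(self, histology_template):
        ph = phantoms.gen_mri_phantom(
            histology_template, n_slices=6, truth_slice=2, warp_amplitude=2.5,
            seed=3, warp_wavelength=48.0, noise_sigma=0.0,
        )
        H, W = histology_template.shape
        gy, gx = np.meshgrid(np.linspace(6, H - 7, 8).astype(int),
                             np.linspace(6, W - 7, 8).astype(int), indexing="ij")
        tgt = np.stack([gy.ravel(), gx.ravel()], 1).astype(float)
        src = tgt + ph.truth_warp[gy.ravel(), gx.ravel()]
        model = R.tps_fit(np.hstack([src, tgt]), smoothing=0.0)
        _, field = R.tps_apply(model, ph.affined, output_shape=(H, W))
        truth_field = (
            np.stack(np.meshgrid(np.arange(H), np.arange(W), indexing="ij"), -1) + ph.truth_warp
        )
        err = np.linalg.norm(field - truth_field, axis=-1)
        tissue = ph.truth_slice_image > 0
        assert (err[tissue] <= 1.0).mean() >= 0.90

    def test_nearest_interpolation_preserves_binary_values(self):
        rng = np.random.default_rng(2)
        binary = (rng.uniform(0, 1, (64, 64)) > 0.5).astype(float)
        tgt = np.array([[r, c] for r in range(0, 64, 12) for c in range(0, 64, 12)], float)
        src = tgt + rng.uniform(-2, 2, tgt.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = R.tps_fit(np.hstack([src, tgt]), smoothing=0.0)
        warped, _ = R.tps_apply(model, binary, interpolation="nearest")
        assert set(np.unique(warped)) <= {0.0, 1.0}


class TestTransformStack:
    def test_empty_folder_warns(self, tmp_path):
        with pytest.warns(UserWarning, match="nothing to transform"):
            report = R.transform_stack(tmp_path, None, None)
        assert report["written"] == []

    def test_threshold_binarize_gives_binary_output(self, tmp_path, histology_template):
        mask = (histology_template > 0.5).astype(np.float32)
        nib.save(R.image_to_slice_nifti(mask), str(tmp_path / "mask.nii.gz"))
        tgt = np.array([[r, c] for r in range(0, 96, 16) for c in range(0, 96, 16)], float)
        rng = np.random.default_rng(0)
        src = tgt + rng.uniform(-1.5, 1.5, tgt.shape)
        model = R.tps_fit(np.hstack([src, tgt]), smoothing=0.0)
        report = R.transform_stack(tmp_path, R.Affine2D.identity(), model,
                                   threshold=0.5, binarize=True)
        out = np.asarray(nib.load(str(report["written"][0])).dataobj)
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_reproduces_direct_tps_result_bit_exactly(self, tmp_path, histology_template):
        nib.save(R.image_to_slice_nifti(histology_template), str(tmp_path / "h.nii.gz"))
        aff = R.Affine2D.from_params(rotation_deg=3, translation=(1, -1), center=(47.5, 47.5))
        tgt = np.array([[r, c] for r in range(4, 96, 12) for c in range(4, 96, 12)], float)
        model = R.tps_fit(np.hstack([tgt + 0.8, tgt]), smoothing=0.0)
        report = R.transform_stack(tmp_path, aff, model)
        out = np.asarray(nib.load(str(report["written"][0])).dataobj)[:, :, 0]
        manual, _ = R.tps_apply(model, aff.warp(histology_template.astype(np.float32)))
        assert np.array_equal(out, manual.astype(np.float32))

    def test_mixed_shapes_reported_and_skipped(self, tmp_path, histology_template):
        nib.save(R.image_to_slice_nifti(histology_template), str(tmp_path / "a.nii.gz"))
        nib.save(R.image_to_slice_nifti(histology_template[:50]), str(tmp_path / "b.nii.gz"))
        report = R.transform_stack(tmp_path, R.Affine2D.identity(), None)
        assert len(report["written"]) == 1
        assert "b.nii.gz" in report["errors"]


class TestSplitMask:
    def test_partition_connectivity_and_balance(self):
        mask = np.ones((50, 100), bool)
        lab = R.split_mask(mask, target_size=500, seed=0)
        sizes = np.array(list(lab.sizes.values()))
        assert len(sizes) == 10
        assert sizes.min() >= 0.7 * 500 and sizes.max() <= 1.3 * 500
        assert ((lab.labels > 0) == mask).all()
        struct = ndimage.generate_binary_structure(2, 1)
        for l in lab.sizes:
            assert ndimage.label(lab.labels == l, structure=struct)[1] == 1

    def test_small_mask_is_single_region(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        lab = R.split_mask(mask, target_size=500, seed=0)
        assert list(lab.sizes.values()) == [100]
        assert ((lab.labels == 1) == mask).all()

    def test_translation_invariant_partition_quality(self):
        base = np.zeros((80, 130), bool)
        base[20:70, 20:120] = True
        lab = R.split_mask(base, target_size=500, seed=0)
        sizes = np.array(list(lab.sizes.values()))
        assert sizes.min() >= 350 and sizes.max() <= 650

    def test_empty_mask_is_error(self):
        with pytest.raises(ValueError):
            R.split_mask(np.zeros((10, 10), bool))

    def test_default_target_size_500(self):
        import inspect

        assert inspect.signature(R.split_mask).parameters["target_size"].default == 500


class TestResample:
    def test_already_on_reference_grid_unchanged(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 1, (12, 10, 8)).astype(np.float32)
        img = nib.Nifti1Image(data, np.diag([1.0, 1.0, 1.0, 1.0]))
        out = R.resample_to_reference(img, img)
        assert np.allclose(np.asarray(out.dataobj), data, atol=1e-6)

    def test_output_grid_equals_reference_exactly(self):
        src = nib.Nifti1Image(np.zeros((20, 18, 16), np.float32), np.diag([1, 1, 1, 1.0]))
        ref = nib.Nifti1Image(np.zeros((10, 9, 8), np.float32), np.diag([2, 2, 2, 1.0]))
        out = R.resample_to_reference(src, ref)
        assert out.shape == ref.shape
        assert tuple(out.header.get_zooms()) == tuple(ref.header.get_zooms())

    def test_linear_ramp_interpolated_exactly(self):
        x = np.arange(32, dtype=np.float32)
        data = np.broadcast_to(x[:, None, None], (32, 8, 8)).copy()
        src = nib.Nifti1Image(data, np.diag([1, 1, 1, 1.0]))
        ref = nib.Nifti1Image(np.zeros((16, 4, 4), np.float32), np.diag([2, 2, 2, 1.0]))
        out = R.resample_to_reference(src, ref)
        vals = np.asarray(out.dataobj)[1:-1, 2, 2]
        expected = 2.0 * np.arange(16)[1:-1]  # analytic ramp at 2 mm spacing
        assert np.abs(vals - expected).max() <= 1e-5

    def test_missing_spacing_is_error(self):
        src = nib.Nifti1Image(np.zeros((4, 4, 4), np.float32), np.eye(4))
        src.header.set_zooms((0.0, 1.0, 1.0))
        ref = nib.Nifti1Image(np.zeros((4, 4, 4), np.float32), np.eye(4))
        with pytest.raises(ValueError):
            R.resample_to_reference(src, ref)


class TestEndToEndRecovery:
    def test_plane_slice_orientation_recovered_top1(self, mri_phantom, histology_template):
        hist = R.preprocess_for_registration(histology_template)
        plane = R.find_plane(mri_phantom.volume)
        match = R.find_best_slice(mri_phantom.volume, hist, metric="nmi", plane_axis=plane)
        sl = np.take(mri_phantom.volume, match.slice_index, axis=plane)
        ranking = R.rank_orientations(hist, sl)
        assert (plane, match.slice_index, ranking[0][0]) == (
            mri_phantom.truth_plane, mri_phantom.truth_slice, mri_phantom.truth_orientation
        )
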