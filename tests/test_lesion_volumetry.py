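import numpy as np
import pytest

from cctpipe.lesions import (
    AffineTransform,
    RigidTransform,
    Volume3D,
    VolumetryError,
    lesion_volume_ml,
    prepare_wm_flair,
    run_lesion_pipeline,
    segment_lesions,
    tissue_volumes_cm3,
)
from cctpipe.lesions.segmentation import TissueMaps
from cctpipe.synth import make_template


def _dice(a, b):
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def _flat_volume(values, shape=(10, 10, 10)):
    return Volume3D(np.asarray(values, dtype=float).reshape(shape), np.eye(4))


class TestLesionVolumeMl:
    def test_paper_voxel_arithmetic(self):
        mask = np.ones((20, 20, 20), dtype=bool)  # 8000 voxels
        assert lesion_volume_ml(mask, (1.0, 0.9, 5.0)) == pytest.approx(36.0)

    def test_empty_mask(self):
        assert lesion_volume_ml(np.zeros((4, 4, 4), bool), (1, 1, 1)) == 0.0

    def test_single_unit_voxel(self):
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        assert lesion_volume_ml(mask, (1.0, 1.0, 1.0)) == pytest.approx(0.001)

    def test_invalid_voxel_size(self):
        with pytest.raises(ValueError):
            lesion_volume_ml(np.ones((2, 2, 2), bool), (1.0, -1.0, 1.0))


class TestSegmentLesions:
    def test_exact_percentile_count_on_distinct_values(self, rng):
        values = rng.permutation(1000).astype(float)
        result = segment_lesions(_flat_volume(values), percentile=95.0)
        assert result.flagged_voxels == 50

    def test_constant_image_flags_nothing_with_warning(self):
        result = segment_lesions(_flat_volume(np.full(1000, 3.0)))
        assert result.flagged_voxels == 0
        assert result.warning is not None

    def test_too_few_retained_voxels_errors(self):
        data = np.full((3, 3, 3), np.nan)
        data[0, 0, 0] = 1.0
        with pytest.raises(VolumetryError, match="retained"):
            segment_lesions(Volume3D(data, np.eye(4)))

    def test_flag_fraction_bounded(self, rng):
        # ties can only reduce the flagged fraction below (100-p)/100
        values = rng.integers(0, 50, size=1000).astype(float)
        result = segment_lesions(_flat_volume(values), percentile=95.0)
        assert result.flagged_voxels <= 50

    def test_threshold_is_linear_interpolation_percentile(self, rng):
        values = rng.normal(size=1000)
        result = segment_lesions(_flat_volume(values))
        assert result.threshold_value == pytest.approx(np.percentile(values, 95))


class TestTissueVolumes:
    def test_pure_wm_block(self):
        shape = (10, 10, 1)  # 100 voxels
        maps = TissueMaps(
            prob_csf=np.zeros(shape),
            prob_gm=np.zeros(shape),
            prob_wm=np.ones(shape),
            brain_mask=np.ones(shape, bool),
        )
        vols = tissue_volumes_cm3(maps, (1.0, 1.0, 1.0))
        assert vols["wm_cm3"] == pytest.approx(0.1)
        assert vols["total_brain_cm3"] == pytest.approx(0.1)

    def test_all_zero_probabilities(self):
        shape = (5, 5, 5)
        maps = TissueMaps(
            prob_csf=np.zeros(shape),
            prob_gm=np.zeros(shape),
            prob_wm=np.zeros(shape),
            brain_mask=np.zeros(shape, bool),
        )
        vols = tissue_volumes_cm3(maps, (1.0, 1.0, 1.0))
        assert all(v == 0.0 for v in vols.values())

    def test_soft_vs_hard_assignment_close(self, small_subject):
        from cctpipe.lesions import segment_tissues

        tissues = segment_tissues(
            small_subject.t1, small_subject.truth_tissues.brain_mask
        )
        soft = tissue_volumes_cm3(tissues, small_subject.t1.voxel_mm)
        hard = tissues.hard_labels()
        vox_cm3 = np.prod(small_subject.t1.voxel_mm) / 1000.0
        for label, key in ((1, "csf_cm3"), (2, "gm_cm3"), (3, "wm_cm3")):
            hard_vol = (hard == label).sum() * vox_cm3
            assert soft[key] == pytest.approx(hard_vol, rel=0.05)


class TestPrepareWmFlair:
    def _inputs(self, subject):
        truth = subject.truth_tissues
        return dict(
            flair=subject.flair,
            tissues=truth,
            t1_affine=subject.t1.affine,
            rigid=subject.applied_rigid,
            atlas_affine=subject.atlas_affine,
            affine_inv=subject.applied_affine,  # identity phantom
        )

    def test_empty_roi_set_equals_wm_masked_flair(self, aligned_subject):
        kw = self._inputs(aligned_subject)
        out = prepare_wm_flair(atlas_rois={}, wm_prob_cut=0.5, **kw)
        retained = np.isfinite(out.data)
        # native-space contract: retained intensities are the raw FLAIR values
        assert np.array_equal(out.data[retained], aligned_subject.flair.data[retained])
        assert out.affine is aligned_subject.flair.affine

    def test_retained_count_set_arithmetic(self, aligned_subject):
        kw = self._inputs(aligned_subject)
        no_roi = prepare_wm_flair(atlas_rois={}, wm_prob_cut=0.5, **kw)
        with_roi = prepare_wm_flair(
            atlas_rois=aligned_subject.atlas_rois, wm_prob_cut=0.5, **kw
        )
        wm_mask = np.isfinite(no_roi.data)
        # oracle: map each ROI onto the FLAIR grid by hand (nearest template
        # voxel of each FLAIR world point; identity transforms) and count
        pts = aligned_subject.flair.world_grid().reshape(-1, 3)
        inv_atlas = np.linalg.inv(aligned_subject.atlas_affine)
        # nearest voxel with ties rounding up (floor(x + 0.5)), the standard
        # nearest-neighbour convention for commensurate grids
        idx = np.floor(pts @ inv_atlas[:3, :3].T + inv_atlas[:3, 3] + 0.5).astype(int)
        excluded = np.zeros(pts.shape[0], dtype=bool)
        for roi in aligned_subject.atlas_rois.values():
            inside = np.all((idx >= 0) & (idx < roi.shape), axis=1)
            sel = idx[inside]
            excluded[inside] |= roi[sel[:, 0], sel[:, 1], sel[:, 2]]
        expected = wm_mask.sum() - np.logical_and(wm_mask.ravel(), excluded).sum()
        assert np.isfinite(with_roi.data).sum() == expected

    def test_wm_prob_cut_one_on_noisy_tissues_errors(self):
        from cctpipe.lesions import segment_tissues
        from cctpipe.synth import PhantomParams, gen_mri_subject

        # heavy noise: class posteriors never saturate to exactly 1.0, so a
        # cut of 1.0 leaves a (near-)empty retained set
        noisy = gen_mri_subject(PhantomParams.small(noise_sd=12.0), seed=13)
        tissues = segment_tissues(noisy.t1, noisy.truth_tissues.brain_mask)
        kw = self._inputs(noisy)
        kw["tissues"] = tissues
        with pytest.raises(VolumetryError):
            prepare_wm_flair(atlas_rois={}, wm_prob_cut=1.0, **kw)


class TestEndToEnd:
    def test_small_phantom_recovery(self, small_subject, small_params):
        template = make_template(small_params)
        result = run_lesion_pipeline(
            small_subject.t1,
            small_subject.flair,
            template,
            small_subject.atlas_rois,
            small_subject.atlas_affine,
        )
        lesions = result["lesions"]
        truth = small_subject.truth_lesion_mask
        truth_ml = small_subject.truth_lesion_volume_ml
        assert _dice(lesions.mask, truth) >= 0.8
        assert lesions.volume_ml == pytest.approx(truth_ml, rel=0.15)

    def test_whole_brain_percentile_support_switch(self, small_subject, small_params):
        template = make_template(small_params)
        result = run_lesion_pipeline(
            small_subject.t1,
            small_subject.flair,
            template,
            small_subject.atlas_rois,
            small_subject.atlas_affine,
            percentile_support="whole_brain",
        )
        # threshold computed over the whole in-brain FLAIR sits below the
        # WM-only threshold (CSF/GM voxels included in the support)
        assert result["lesions"].mask.sum() > 0
        with pytest.raises(ValueError):
            run_lesion_pipeline(
                small_subject.t1,
                small_subject.flair,
                template,
                small_subject.atlas_rois,
                small_subject.atlas_affine,
                percentile_support="bogus",
            )
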