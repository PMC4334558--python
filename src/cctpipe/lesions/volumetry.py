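"""Native-space white-matter lesion segmentation and tissue volumetry.

The FLAIR volume is never resampled: the white-matter map and the template
exclusion ROIs are brought *into* the FLAIR grid, the retained voxels are
thresholded at a percentile of their own intensity distribution, and volumes
are read off the native voxel geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .registration import register_affine_to_template, register_rigid
from .segmentation import SegmentationError, TissueMaps, extract_brain, segment_tissues
from .volume import AffineTransform, RigidTransform, Volume3D, resample


class VolumetryError(RuntimeError):
    pass


@dataclass(frozen=True)
class LesionResult:
    """Binary lesion mask with its realised threshold and volume."""

    mask: np.ndarray
    volume_ml: float
    threshold_value: float
    retained_voxels: int
    flagged_voxels: int
    warning: str | None = None


def lesion_volume_ml(mask: np.ndarray, voxel_mm) -> float:
    """Voxel count times voxel volume, in millilitres."""
    voxel_mm = np.asarray(voxel_mm, dtype=float)
    if np.any(voxel_mm <= 0):
        raise ValueError("voxel_mm must be positive")
    return float(np.count_nonzero(mask) * np.prod(voxel_mm) / 1000.0)


def tissue_volumes_cm3(tissues: TissueMaps, voxel_mm) -> dict[str, float]:
    """Probabilistic tissue volumes in cm^3; total brain = GM + WM."""
    voxel_mm = np.asarray(voxel_mm, dtype=float)
    vox_cm3 = float(np.prod(voxel_mm)) / 1000.0
    gm = float(tissues.prob_gm.sum()) * vox_cm3
    wm = float(tissues.prob_wm.sum()) * vox_cm3
    csf = float(tissues.prob_csf.sum()) * vox_cm3
    return {
        "gm_cm3": gm,
        "wm_cm3": wm,
        "csf_cm3": csf,
        "total_brain_cm3": gm + wm,
    }


def prepare_wm_flair(
    flair: Volume3D,
    tissues: TissueMaps,
    t1_affine: np.ndarray,
    rigid: RigidTransform,
    atlas_rois: Mapping[str, np.ndarray],
    atlas_affine: np.ndarray,
    affine_inv: AffineTransform,
    wm_prob_cut: float = 0.5,
) -> Volume3D:
    """Mask the FLAIR to white matter minus template exclusion ROIs.

    * WM probabilities (on the T1 grid with ``t1_affine``) are pulled onto the
      FLAIR grid through the rigid T1->FLAIR map (trilinear) and binarised at
      ``wm_prob_cut``.
    * Each template-space ROI is mapped template -> native T1 via
      ``affine_inv`` and on to the FLAIR grid via the rigid map
      (nearest-neighbour), then removed from the retained region.
    * The output equals the input FLAIR inside the retained region and NaN
      elsewhere; the FLAIR intensities themselves are never resampled.
    """
    wm_vol = Volume3D(tissues.prob_wm, t1_affine)
    # fixed (FLAIR) world -> moving (T1) world is the inverse rigid map
    wm_on_flair = resample(wm_vol, flair, world_map=rigid.inverse_matrix(), order=1)
    retained = wm_on_flair >= wm_prob_cut

    if atlas_rois:
        # fixed (FLAIR) world -> T1 world -> template world
        to_template = affine_inv.inverse().matrix @ rigid.inverse_matrix()
        for name, roi in atlas_rois.items():
            roi_vol = Volume3D(np.asarray(roi, dtype=np.float64), atlas_affine)
            mapped = resample(roi_vol, flair, world_map=to_template, order=0)
            retained &= ~(mapped > 0.5)

    if not np.any(retained):
        raise VolumetryError("no voxels retained after WM masking and ROI exclusion")
    out = np.where(retained, flair.data, np.nan)
    return Volume3D(out, flair.affine)


def segment_lesions(wm_flair: Volume3D, percentile: float = 95.0) -> LesionResult:
    """Flag retained voxels strictly brighter than the given percentile.

    The threshold is the linear-interpolation percentile of the retained
    (finite) voxel intensities; a constant retained image yields an empty mask
    with a warning rather than an error.
    """
    retained = np.isfinite(wm_flair.data)
    values = wm_flair.data[retained]
    if values.size < 20:
        raise VolumetryError(
            f"only {values.size} retained voxels; percentile is not meaningful"
        )
    threshold = float(np.percentile(values, percentile))
    mask = np.zeros(wm_flair.shape, dtype=bool)
    mask[retained] = wm_flair.data[retained] > threshold
    warning = None
    if not mask.any():
        warning = "no voxel strictly exceeds the percentile threshold"
    return LesionResult(
        mask=mask,
        volume_ml=lesion_volume_ml(mask, wm_flair.voxel_mm),
        threshold_value=threshold,
        retained_voxels=int(values.size),
        flagged_voxels=int(mask.sum()),
        warning=warning,
    )


def run_lesion_pipeline(
    t1: Volume3D,
    flair: Volume3D,
    template: Volume3D,
    atlas_rois: Mapping[str, np.ndarray],
    atlas_affine: np.ndarray,
    percentile: float = 95.0,
    wm_prob_cut: float = 0.5,
    percentile_support: str = "wm_only",
    seed: int = 0,
) -> dict:
    """Run coregistration -> segmentation -> normalisation -> lesion volumetry.

    ``percentile_support`` selects the intensity support of the lesion
    threshold: ``"wm_only"`` (retained WM voxels, the default) or
    ``"whole_brain"`` (all in-brain FLAIR voxels mapped through the brain
    mask); the lesion mask itself is always restricted to the retained region.
    """
    if percentile_support not in ("wm_only", "whole_brain"):
        raise ValueError(f"unknown percentile_support {percentile_support!r}")
    rigid = register_rigid(t1, flair)
    brain = extract_brain(t1)
    tissues = segment_tissues(t1, brain, seed=seed)
    affine_fwd = register_affine_to_template(t1, template)
    wm_flair = prepare_wm_flair(
        flair,
        tissues,
        t1.affine,
        rigid,
        atlas_rois,
        atlas_affine,
        affine_fwd.inverse(),
        wm_prob_cut=wm_prob_cut,
    )
    if percentile_support == "whole_brain":
        brain_vol = Volume3D(brain.astype(np.float64), t1.affine)
        brain_on_flair = resample(brain_vol, flair, world_map=rigid.inverse_matrix(), order=0)
        support = flair.data[brain_on_flair > 0.5]
        threshold = float(np.percentile(support, percentile))
        retained = np.isfinite(wm_flair.data)
        mask = retained & (np.nan_to_num(wm_flair.data, nan=-np.inf) > threshold)
        lesions = LesionResult(
            mask=mask,
            volume_ml=lesion_volume_ml(mask, flair.voxel_mm),
            threshold_value=threshold,
            retained_voxels=int(retained.sum()),
            flagged_voxels=int(mask.sum()),
        )
    else:
        lesions = segment_lesions(wm_flair, percentile=percentile)
    volumes = tissue_volumes_cm3(tissues, t1.voxel_mm)
    return {
        "rigid": rigid,
        "tissues": tissues,
        "affine_to_template": affine_fwd,
        "wm_flair": wm_flair,
        "lesions": lesions,
        "volume_ml": lesions.volume_ml,
        "threshold_value": lesions.threshold_value,
        **volumes,
    }
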