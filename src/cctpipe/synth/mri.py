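"""Synthetic head phantoms: T1/FLAIR pairs with known tissue maps, planted
white-matter lesions, a template, and geometric exclusion-ROI "atlas".

Anatomy is a set of nested ellipsoids defined analytically in template
coordinates (RAS mm, origin at the brain centre), so it can be evaluated on
any grid without interpolation: the T1 grid sees the anatomy through the
subject's ``applied_affine``, the FLAIR grid additionally through the
``applied_rigid`` inter-scan motion.  Lesions are grown voxel-wise on the
FLAIR grid inside white matter until a target volume is met.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from ..lesions.segmentation import TissueMaps
from ..lesions.volume import AffineTransform, RigidTransform, Volume3D, apply_homogeneous

LABEL_BG, LABEL_SKULL, LABEL_CSF, LABEL_GM, LABEL_WM = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class PhantomGeometry:
    """Ellipsoid radii (mm) of the anatomy in template coordinates.

    The axes are deliberately distinct (head-like: longest antero-posterior)
    and the ventricles sit off-centre, so the anatomy carries enough
    rotational asymmetry for intensity-based registration to lock on.
    """

    brain_radii_mm: tuple[float, float, float] = (62.0, 78.0, 50.0)
    wm_radii_mm: tuple[float, float, float] = (42.2, 53.1, 34.1)
    wm_center_mm: tuple[float, float, float] = (3.0, 5.0, 4.0)
    csf_radii_mm: tuple[float, float, float] = (12.0, 16.0, 8.0)
    csf_center_mm: tuple[float, float, float] = (0.0, 10.0, 7.0)
    skull_thickness_mm: float = 4.0


@dataclass(frozen=True)
class PhantomParams:
    """Acquisition geometry, tissue intensities and lesion load of a phantom.

    ``grid_shape``/``voxel_mm`` describe the FLAIR grid (paper geometry
    1 x 0.9 x 5 mm); the T1 grid is derived to cover the same field of view at
    ``t1_voxel_mm``.
    """

    grid_shape: tuple[int, int, int] = (140, 190, 30)
    voxel_mm: tuple[float, float, float] = (1.0, 0.9, 5.0)
    t1_voxel_mm: tuple[float, float, float] = (1.3, 1.3, 1.2)
    tissue_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "t1": {"csf": 30.0, "gm": 60.0, "wm": 90.0},
            "flair": {"csf": 10.0, "gm": 70.0, "wm": 55.0},
        }
    )
    lesion_intensity: float = 110.0
    skull_intensity: float = 8.0
    noise_sd: float = 3.0
    lesion_count: int = 8
    lesion_total_ml: float = 15.3
    applied_rigid: RigidTransform = field(default_factory=RigidTransform.identity)
    applied_affine: AffineTransform = field(default_factory=AffineTransform.identity)
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_mm) or any(v <= 0 for v in self.t1_voxel_mm):
            raise ValueError("voxel sizes must be positive")
        if self.lesion_total_ml < 0:
            raise ValueError("lesion_total_ml must be >= 0")
        if self.lesion_total_ml > 0 and self.lesion_count < 1:
            raise ValueError("lesion_count must be >= 1 for a nonzero lesion load")
        if self.lesion_total_ml > 0 and (
            self.lesion_intensity <= self.tissue_means["flair"]["wm"]
        ):
            raise ValueError("FLAIR lesion intensity must exceed the WM mean")

    @classmethod
    def small(cls, **overrides) -> "PhantomParams":
        """A coarse, fast phantom for unit tests (same anatomy, 4x fewer voxels)."""
        defaults = dict(
            grid_shape=(72, 96, 30),
            voxel_mm=(2.0, 1.8, 5.0),
            t1_voxel_mm=(2.6, 2.6, 2.4),
            lesion_total_ml=15.3,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class MriSubject:
    """One synthetic patient: volumes, truth maps, and applied transforms."""

    t1: Volume3D
    flair: Volume3D
    truth_tissues: TissueMaps
    truth_lesion_mask: np.ndarray  # FLAIR grid
    truth_lesion_volume_ml: float
    applied_rigid: RigidTransform
    applied_affine: AffineTransform
    atlas_rois: dict[str, np.ndarray]  # template grid
    atlas_affine: np.ndarray
    params: PhantomParams


def _centered_affine(shape, voxel_mm) -> np.ndarray:
    """Axis-aligned affine placing the FOV centre at the world origin."""
    shape = np.asarray(shape, dtype=float)
    voxel_mm = np.asarray(voxel_mm, dtype=float)
    out = np.eye(4)
    out[:3, :3] = np.diag(voxel_mm)
    out[:3, 3] = -voxel_mm * (shape - 1.0) / 2.0
    return out


def _ellipsoid_r2(pts: np.ndarray, center, radii) -> np.ndarray:
    d = (pts - np.asarray(center, dtype=float)) / np.asarray(radii, dtype=float)
    return np.einsum("ij,ij->i", d, d)


def anatomy_labels(template_pts: np.ndarray, geom: PhantomGeometry) -> np.ndarray:
    """Tissue label for each template-space point, shape ``(N,)``."""
    r_brain = _ellipsoid_r2(template_pts, (0, 0, 0), geom.brain_radii_mm)
    r_shell = _ellipsoid_r2(
        template_pts,
        (0, 0, 0),
        tuple(r + geom.skull_thickness_mm for r in geom.brain_radii_mm),
    )
    labels = np.full(template_pts.shape[0], LABEL_BG, dtype=np.int8)
    labels[r_shell <= 1.0] = LABEL_SKULL
    labels[r_brain <= 1.0] = LABEL_GM
    labels[
        _ellipsoid_r2(template_pts, geom.wm_center_mm, geom.wm_radii_mm) <= 1.0
    ] = LABEL_WM
    labels[
        _ellipsoid_r2(template_pts, geom.csf_center_mm, geom.csf_radii_mm) <= 1.0
    ] = LABEL_CSF
    return labels


_ATLAS_SPEC = {
    # name -> (center mm, radii mm); anatomy-free geometric stand-ins for the
    # structures excluded before lesion thresholding
    "cerebellum": ((0.0, -42.0, -38.0), (26.0, 18.0, 16.0)),
    "brainstem": ((0.0, -12.0, -40.0), (9.0, 9.0, 22.0)),
    "thalamus_l": ((-10.0, -8.0, 0.0), (8.0, 9.0, 7.0)),
    "thalamus_r": ((10.0, -8.0, 0.0), (8.0, 9.0, 7.0)),
    "caudate_l": ((-14.0, 8.0, 5.0), (5.0, 8.0, 6.0)),
    "caudate_r": ((14.0, 8.0, 5.0), (5.0, 8.0, 6.0)),
    "putamen_l": ((-22.0, 2.0, 0.0), (5.0, 7.0, 7.0)),
    "putamen_r": ((22.0, 2.0, 0.0), (5.0, 7.0, 7.0)),
}


def make_atlas(params: PhantomParams) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Template-space exclusion ROI masks and the template affine."""
    template = make_template(params)
    pts = template.world_grid().reshape(-1, 3)
    rois = {}
    for name, (center, radii) in _ATLAS_SPEC.items():
        rois[name] = (_ellipsoid_r2(pts, center, radii) <= 1.0).reshape(template.shape)
    return rois, template.affine


def _intensity_from_labels(labels, means: Mapping[str, float], skull: float) -> np.ndarray:
    lut = np.array([0.0, skull, means["csf"], means["gm"], means["wm"]])
    return lut[labels]


def _t1_grid(params: PhantomParams) -> tuple[tuple[int, int, int], np.ndarray]:
    fov = np.asarray(params.grid_shape, float) * np.asarray(params.voxel_mm, float)
    shape = tuple(int(np.ceil(f / v)) for f, v in zip(fov, params.t1_voxel_mm))
    return shape, _centered_affine(shape, params.t1_voxel_mm)


def make_template(params: PhantomParams) -> Volume3D:
    """Noise-free canonical T1 phantom on the T1 grid (the normalisation target)."""
    shape, affine = _t1_grid(params)
    vol = Volume3D(np.zeros(shape), affine)
    labels = anatomy_labels(vol.world_grid().reshape(-1, 3), params.geometry)
    data = _intensity_from_labels(
        labels, params.tissue_means["t1"], params.skull_intensity
    ).reshape(shape)
    return Volume3D(data, affine)


def _grow_lesions(
    wm_flat: np.ndarray,
    world_pts: np.ndarray,
    n_target: int,
    n_seeds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow ``n_target`` lesion voxels around random seeds, inside WM only.

    All lesions grow jointly by physical distance to their nearest seed; ties
    resolve by voxel index, so the result is deterministic given the seeds.
    """
    wm_idx = np.flatnonzero(wm_flat)
    if n_target > wm_idx.size:
        raise ValueError(
            f"lesion load of {n_target} voxels exceeds available WM ({wm_idx.size} voxels)"
        )
    seeds = rng.choice(wm_idx, size=min(n_seeds, wm_idx.size), replace=False)
    d2 = np.min(
        ((world_pts[wm_idx, None, :] - world_pts[seeds][None, :, :]) ** 2).sum(axis=2),
        axis=1,
    )
    order = np.lexsort((wm_idx, d2))
    chosen = wm_idx[order[:n_target]]
    out = np.zeros(wm_flat.shape, dtype=bool)
    out[chosen] = True
    return out


def gen_mri_subject(params: PhantomParams, seed: int = 0) -> MriSubject:
    """Generate one synthetic patient with known ground truth.

    The FLAIR is simulated on its own grid after the subject "moves" by
    ``applied_rigid`` between scans; the T1 sees the anatomy through
    ``applied_affine`` (template -> subject world).  Truth tissue maps live on
    the T1 grid, the truth lesion mask on the FLAIR grid, and the truth lesion
    volume matches ``lesion_total_ml`` to within one voxel volume.
    """
    rng = np.random.default_rng(seed)
    geom = params.geometry
    affine_inv = np.linalg.inv(params.applied_affine.matrix)  # subject -> template

    # --- T1 grid ---------------------------------------------------------
    t1_shape, t1_affine = _t1_grid(params)
    t1_vol = Volume3D(np.zeros(t1_shape), t1_affine)
    t1_world = t1_vol.world_grid().reshape(-1, 3)
    t1_labels = anatomy_labels(apply_homogeneous(affine_inv, t1_world), geom)
    t1_data = _intensity_from_labels(
        t1_labels, params.tissue_means["t1"], params.skull_intensity
    )
    if params.noise_sd > 0:
        t1_data = t1_data + rng.normal(0.0, params.noise_sd, t1_data.shape)
    t1 = Volume3D(t1_data.reshape(t1_shape), t1_affine)

    labels3d = t1_labels.reshape(t1_shape)
    brain = labels3d >= LABEL_CSF
    truth_tissues = TissueMaps(
        prob_csf=(labels3d == LABEL_CSF).astype(float),
        prob_gm=(labels3d == LABEL_GM).astype(float),
        prob_wm=(labels3d == LABEL_WM).astype(float),
        brain_mask=brain,
        means=tuple(params.tissue_means["t1"][k] for k in ("csf", "gm", "wm")),
        sds=(params.noise_sd,) * 3,
    )

    # --- FLAIR grid ------------------------------------------------------
    fl_affine = _centered_affine(params.grid_shape, params.voxel_mm)
    fl_vol = Volume3D(np.zeros(params.grid_shape), fl_affine)
    fl_world = fl_vol.world_grid().reshape(-1, 3)
    # FLAIR world -> subject T1 world -> template coordinates
    to_subject = params.applied_rigid.inverse_matrix()
    fl_template = apply_homogeneous(affine_inv @ to_subject, fl_world)
    fl_labels = anatomy_labels(fl_template, geom)
    fl_data = _intensity_from_labels(
        fl_labels, params.tissue_means["flair"], params.skull_intensity
    )

    # --- lesions (FLAIR grid, inside WM) ---------------------------------
    voxel_ml = float(np.prod(params.voxel_mm)) / 1000.0
    n_target = int(round(params.lesion_total_ml / voxel_ml))
    if n_target > 0:
        wm3d = (fl_labels == LABEL_WM).reshape(params.grid_shape)
        wm_eroded = ndimage.binary_erosion(wm3d, iterations=1)
        if not wm_eroded.any():
            wm_eroded = wm3d
        lesion_flat = _grow_lesions(
            wm_eroded.ravel(), fl_world, n_target, params.lesion_count, rng
        )
        fl_data = np.where(lesion_flat, params.lesion_intensity, fl_data)
        lesion_mask = lesion_flat.reshape(params.grid_shape)
    else:
        lesion_mask = np.zeros(params.grid_shape, dtype=bool)

    if params.noise_sd > 0:
        fl_data = fl_data + rng.normal(0.0, params.noise_sd, fl_data.shape)
    flair = Volume3D(fl_data.reshape(params.grid_shape), fl_affine)

    atlas_rois, atlas_affine = make_atlas(params)
    return MriSubject(
        t1=t1,
        flair=flair,
        truth_tissues=truth_tissues,
        truth_lesion_mask=lesion_mask,
        truth_lesion_volume_ml=float(lesion_mask.sum()) * voxel_ml,
        applied_rigid=params.applied_rigid,
        applied_affine=params.applied_affine,
        atlas_rois=atlas_rois,
        atlas_affine=atlas_affine,
        params=params,
    )
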