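"""Intensity-based rigid and affine registration.

Rigid coregistration (T1 -> FLAIR) maximises mutual information on a joint
intensity histogram, optimised coarse-to-fine over a multi-resolution pyramid
with a derivative-free Powell search.  Template normalisation initialises a
12-parameter affine by moment matching (centroid + per-axis spread) before the
same MI refinement.  Both are deterministic given their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .volume import (
    AffineTransform,
    RigidTransform,
    Volume3D,
    downsample,
    resample,
)


class RegistrationError(RuntimeError):
    """Raised when the optimiser fails to produce a usable transform."""


_MI_BINS = 48


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = _MI_BINS) -> float:
    """Mutual information (nats) of two paired intensity samples."""
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    total = joint.sum()
    if total == 0:
        return 0.0
    p = joint / total
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    return float(np.sum(p[nz] * (np.log(p[nz]) - np.log(np.outer(px, py)[nz]))))


def _level_factors(fixed: Volume3D, target_mm: float) -> tuple[int, int, int]:
    """Per-axis integer downsampling so level voxels approach ``target_mm``."""
    return tuple(max(1, int(round(target_mm / v))) for v in fixed.voxel_mm)


def _smooth(vol: Volume3D, sigma_mm: float) -> Volume3D:
    """Gaussian blur in world units; tames MI aliasing from hard edges."""
    if sigma_mm <= 0:
        return vol
    sigma_vox = [sigma_mm / v for v in vol.voxel_mm]
    return Volume3D(ndimage.gaussian_filter(vol.data, sigma_vox), vol.affine)


def _neg_mi(fixed_level: Volume3D, moving: Volume3D, world_map: np.ndarray) -> float:
    sampled = resample(moving, fixed_level, world_map=world_map, order=1, cval=np.nan)
    valid = np.isfinite(sampled)
    if valid.sum() < 64:
        return 0.0
    return -mutual_information(fixed_level.data[valid], sampled[valid])


def _foreground(vol: Volume3D) -> np.ndarray:
    from skimage.filters import threshold_otsu

    if np.ptp(vol.data) == 0:
        raise RegistrationError("degenerate intensity histogram (constant volume)")
    return vol.data > threshold_otsu(vol.data)


def _intensity_centroid(vol: Volume3D) -> np.ndarray:
    """World centroid of the Otsu foreground (robust to background noise)."""
    idx = np.array(ndimage.center_of_mass(_foreground(vol)))
    return (vol.affine[:3, :3] @ idx) + vol.affine[:3, 3]


def _intensity_spread(vol: Volume3D) -> np.ndarray:
    """Per-world-axis standard deviation (mm) of the Otsu foreground."""
    fg = _foreground(vol).ravel()
    pts = vol.world_grid().reshape(-1, 3)[fg]
    return pts.std(axis=0)


def register_rigid(
    moving: Volume3D,
    fixed: Volume3D,
    pyramid_mm: tuple[float, ...] = (6.0, 3.0),
    max_iter: int = 40,
) -> RigidTransform:
    """Recover the 6-parameter rigid world map ``moving -> fixed``.

    Raises :class:`RegistrationError` when either volume has a degenerate
    intensity histogram or the final similarity indicates no overlap.
    """
    center = tuple(fixed.world_center())
    t0 = _intensity_centroid(fixed) - _intensity_centroid(moving)
    params = np.array([0.0, 0.0, 0.0, *t0])

    def matrix_of(p: np.ndarray) -> np.ndarray:
        return RigidTransform(tuple(p[:3]), tuple(p[3:6]), center).inverse_matrix()

    last_value = np.inf
    for target in pyramid_mm:
        sigma = target / 2.0
        level = _smooth(downsample(fixed, _level_factors(fixed, target)), sigma)
        mov = _smooth(moving, sigma)
        res = optimize.minimize(
            lambda p: _neg_mi(level, mov, matrix_of(p)),
            params,
            method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-5, "maxiter": max_iter},
        )
        params = res.x
        last_value = float(res.fun)
    if last_value >= -1e-3:
        raise RegistrationError(
            f"rigid registration did not converge (final MI {-last_value:.4g})"
        )
    return RigidTransform(tuple(params[:3]), tuple(params[3:6]), center)


def register_affine_to_template(
    t1: Volume3D,
    template: Volume3D,
    pyramid_mm: tuple[float, ...] = (10.0, 5.0),
    max_iter: int = 15,
) -> AffineTransform:
    """12-parameter affine normalisation ``t1 world -> template world``.

    Moment matching (intensity centroid + per-axis spread ratio) provides the
    starting point; MI refinement handles rotation/shear.  The inverse (for
    mapping template-space ROIs into native space) is ``result.inverse()``.
    """
    center = tuple(template.world_center())
    spread_ratio = _intensity_spread(template) / _intensity_spread(t1)
    t0 = _intensity_centroid(template) - _intensity_centroid(t1)
    # params: 3 rotations deg, 3 translations mm, 3 log-scales, 3 shears
    params = np.array([0.0, 0.0, 0.0, *t0, *np.log(spread_ratio), 0.0, 0.0, 0.0])

    def transform_of(p: np.ndarray) -> AffineTransform:
        return AffineTransform.from_params(
            rotations_deg=tuple(p[:3]),
            translation_mm=tuple(p[3:6]),
            scales=tuple(np.exp(p[6:9])),
            shears=tuple(p[9:12]),
            center=center,
        )

    for target in pyramid_mm:
        sigma = target / 2.0
        level = _smooth(downsample(template, _level_factors(template, target)), sigma)
        mov = _smooth(t1, sigma)
        res = optimize.minimize(
            lambda p: _neg_mi(level, mov, np.linalg.inv(transform_of(p).matrix)),
            params,
            method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-5, "maxiter": max_iter},
        )
        params = res.x
    out = transform_of(params)
    # contract: composing with the inverse must be identity to < 0.5 voxel
    comp = out.matrix @ out.inverse().matrix
    probe = template.world_grid()[:: max(1, template.shape[0] // 4)].reshape(-1, 3)
    disp = np.abs(probe @ comp[:3, :3].T + comp[:3, 3] - probe).max()
    if disp > 0.5 * float(min(template.voxel_mm)):
        raise RegistrationError("affine inverse composition exceeds 0.5 voxel")
    return out
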