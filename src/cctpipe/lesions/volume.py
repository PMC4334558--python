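"""3-D volumes with world affines, rigid/affine transforms, and resampling.

Conventions
-----------
* Voxel indices are 0-based ``(i, j, k)`` column vectors; ``affine @ [i,j,k,1]``
  gives RAS world coordinates in millimetres.
* A :class:`RigidTransform` or :class:`AffineTransform` maps *world* points of
  the moving image into *world* points of the fixed image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class TransformError(ValueError):
    """Raised for non-invertible or otherwise degenerate transforms."""


@dataclass(frozen=True)
class Volume3D:
    """An intensity volume on a regular grid with a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        affine = np.asarray(self.affine, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {data.shape}")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise TransformError("affine is not invertible")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_center(self) -> np.ndarray:
        """World coordinates of the geometric centre of the field of view."""
        c = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return apply_homogeneous(self.affine, c[None, :])[0]

    def world_grid(self) -> np.ndarray:
        """World coordinates for every voxel, shape ``(X, Y, Z, 3)``."""
        idx = np.indices(self.shape, dtype=np.float64)
        pts = idx.reshape(3, -1).T
        world = apply_homogeneous(self.affine, pts)
        return world.reshape(*self.shape, 3)


def apply_homogeneous(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 4x4 homogeneous matrix to an ``(N, 3)`` array of points."""
    points = np.asarray(points, dtype=np.float64)
    return points @ matrix[:3, :3].T + matrix[:3, 3]


def _rotation_matrix(rx_deg: float, ry_deg: float, rz_deg: float) -> np.ndarray:
    rx, ry, rz = np.deg2rad([rx_deg, ry_deg, rz_deg])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return mz @ my @ mx


@dataclass(frozen=True)
class RigidTransform:
    """6-parameter rigid map: rotation (degrees) about ``center``, then shift.

    ``w' = R (w - center) + center + t``
    """

    rotations_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        rot = _rotation_matrix(*self.rotations_deg)
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation_mm, dtype=float)
        out = np.eye(4)
        out[:3, :3] = rot
        out[:3, 3] = c + t - rot @ c
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        return apply_homogeneous(self.matrix, points)

    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()


@dataclass(frozen=True)
class AffineTransform:
    """A general invertible 12-parameter (4x4) world-to-world map."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=np.float64)
        if matrix.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        if abs(np.linalg.det(matrix[:3, :3])) < 1e-12:
            raise TransformError("affine transform is not invertible")
        object.__setattr__(self, "matrix", matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return apply_homogeneous(self.matrix, points)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_params(
        cls,
        rotations_deg=(0.0, 0.0, 0.0),
        translation_mm=(0.0, 0.0, 0.0),
        scales=(1.0, 1.0, 1.0),
        shears=(0.0, 0.0, 0.0),
        center=(0.0, 0.0, 0.0),
    ) -> "AffineTransform":
        """Compose rotation @ shear @ scale about ``center`` plus translation."""
        rot = _rotation_matrix(*rotations_deg)
        sh = np.eye(3)
        sh[0, 1], sh[0, 2], sh[1, 2] = shears
        sc = np.diag(scales)
        lin = rot @ sh @ sc
        c = np.asarray(center, dtype=float)
        t = np.asarray(translation_mm, dtype=float)
        out = np.eye(4)
        out[:3, :3] = lin
        out[:3, 3] = c + t - lin @ c
        return cls(out)


def resample(
    moving: Volume3D,
    fixed: Volume3D,
    world_map: np.ndarray | None = None,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Pull ``moving`` intensities onto the grid of ``fixed``.

    ``world_map`` maps fixed-image world points to moving-image world points
    (i.e. the *inverse* of the moving-to-fixed transform). ``order=0`` selects
    nearest-neighbour (labels), ``order=1`` trilinear (intensities).
    """
    if world_map is None:
        world_map = np.eye(4)
    full = np.linalg.inv(moving.affine) @ world_map @ fixed.affine
    return ndimage.affine_transform(
        moving.data,
        matrix=full[:3, :3],
        offset=full[:3, 3],
        output_shape=fixed.shape,
        order=order,
        mode="constant",
        cval=cval,
        prefilter=order <= 1,
    )


def downsample(vol: Volume3D, factors: tuple[int, int, int]) -> Volume3D:
    """Block-mean downsample by integer factors, keeping the affine consistent.

    New voxel ``i`` covers old voxels ``[f*i, f*i + f)`` so its centre sits at
    old index ``f*i + (f-1)/2``.
    """
    f = np.asarray(factors, dtype=int)
    if np.all(f == 1):
        return vol
    data = vol.data
    pad = [(0, (-s) % fi) for s, fi in zip(data.shape, f)]
    if any(p[1] for p in pad):
        data = np.pad(data, pad, mode="edge")
    sx, sy, sz = (data.shape[i] // f[i] for i in range(3))
    data = data.reshape(sx, f[0], sy, f[1], sz, f[2]).mean(axis=(1, 3, 5))
    step = np.eye(4)
    step[:3, :3] = np.diag(f.astype(float))
    step[:3, 3] = (f - 1) / 2.0
    return Volume3D(data, vol.affine @ step)
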