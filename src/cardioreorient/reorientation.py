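"""Rotation to short-axis orientation by affine resampling.

Two rotation matrices are built from the deflection angles — H1, a rotation
about the x-axis by alpha, and H2, a rotation about the y-axis by beta:

    H1 = [[1, 0, 0], [0, cos a, -sin a], [0, sin a, cos a]]
    H2 = [[cos b, 0, sin b], [0, 1, 0], [-sin b, 0, cos b]]

Their composition R = H2 . H1 maps the body z-axis onto the ventricular
long axis; resampling the volume through R (pull-back warping about the
ventricle center, in physical mm space so anisotropic voxels are handled)
aligns the long axis with z, yielding the short-axis stack.  Horizontal and
vertical long-axis views are the mid-planes of that stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_volume import Volume3D
from .ellipsoid_fit import DeflectionAngles


@dataclass(frozen=True)
class RotationMatrices:
    H1: np.ndarray
    H2: np.ndarray

    @property
    def R(self) -> np.ndarray:
        return self.H2 @ self.H1

    def __post_init__(self):
        for M in (self.H1, self.H2, self.R):
            if not np.allclose(M @ M.T, np.eye(3), atol=1e-10):
                raise ValueError("rotation matrix is not orthonormal")
            if not np.isclose(np.linalg.det(M), 1.0, atol=1e-10):
                raise ValueError("rotation matrix determinant != +1")


def rotation_matrices_from_degrees(alpha_deg: float, beta_deg: float) -> RotationMatrices:
    a = np.radians(alpha_deg)
    b = np.radians(beta_deg)
    H1 = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, np.cos(a), -np.sin(a)],
            [0.0, np.sin(a), np.cos(a)],
        ]
    )
    H2 = np.array(
        [
            [np.cos(b), 0.0, np.sin(b)],
            [0.0, 1.0, 0.0],
            [-np.sin(b), 0.0, np.cos(b)],
        ]
    )
    return RotationMatrices(H1, H2)


def rotation_matrices(angles: DeflectionAngles) -> RotationMatrices:
    """Build H1(alpha), H2(beta) and their composition from deflection angles."""
    if not (np.isfinite(angles.alpha) and np.isfinite(angles.beta)):
        raise ValueError("angles must be finite")
    return rotation_matrices_from_degrees(angles.alpha, angles.beta)


@dataclass
class ReorientResult:
    sa: Volume3D
    hla: np.ndarray
    vla: np.ndarray
    angles: DeflectionAngles
    center_mm: tuple[float, float, float]


def reorient(
    vol: Volume3D,
    angles: DeflectionAngles,
    center: str | tuple[float, float, float] = "grid_center",
    interp: str = "trilinear",
    mask: np.ndarray | None = None,
) -> ReorientResult:
    """Resample ``vol`` so the ventricular long axis becomes the z-axis.

    Pull-back warping: each output voxel p is sampled at R(p - c) + c in the
    input (physical mm coordinates, zero fill outside), with R = H2 . H1.
    ``center`` is ``"grid_center"``, ``"lv_centroid"`` (intensity centroid,
    or centroid of ``mask`` when given), or an explicit (x, y, z) mm tuple.
    The output grid equals the input grid, so the short-axis stack keeps the
    divided volume's shape; the apex ends at the highest z indices.
    """
    if interp not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    R = rotation_matrices(angles).R
    spacing = np.asarray(vol.spacing)
    if isinstance(center, str):
        if center == "grid_center":
            c_mm = (np.asarray(vol.shape) - 1) / 2.0 * spacing
        elif center == "lv_centroid":
            w = mask.astype(np.float64) if mask is not None else vol.data
            tot = w.sum()
            if tot <= 0:
                c_mm = (np.asarray(vol.shape) - 1) / 2.0 * spacing
            else:
                idx = np.indices(vol.shape).reshape(3, -1)
                c_mm = (idx * w.reshape(1, -1)).sum(axis=1) / tot * spacing
        else:
            raise ValueError(f"unknown center mode {center!r}")
    else:
        c_mm = np.asarray(center, dtype=np.float64)

    # index-space affine: i_in = S^-1 R S (i_out - c_idx) + c_idx
    S = np.diag(spacing)
    Sinv = np.diag(1.0 / spacing)
    M = Sinv @ R @ S
    c_idx = c_mm / spacing
    offset = c_idx - M @ c_idx
    order = 1 if interp == "trilinear" else 0
    data = ndimage.affine_transform(vol.data, M, offset=offset, order=order, mode="constant", cval=0.0)
    data = np.clip(data, 0.0, None)
    sa = Volume3D(data, vol.spacing, vol.origin)
    hla = data[data.shape[0] // 2, :, :]  # y-z plane at mid-x
    vla = data[:, data.shape[1] // 2, :]  # x-z plane at mid-y
    return ReorientResult(sa, hla.copy(), vla.copy(), angles, tuple(float(v) for v in c_mm))
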