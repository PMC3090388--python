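"""Rotations, projection and back-projection primitives.

Euler convention (used everywhere in the package): intrinsic ZYZ
(rot, tilt, psi) in degrees, ``R = Rz(rot) @ Ry(tilt) @ Rz(psi)``.  The
volume is rotated actively by ``R^T`` and projected along +z, so the
viewing direction in the particle frame is ``R z`` — fixed by (rot, tilt)
alone — and ``psi`` is the in-plane rotation of the projection.  A
particle-frame point q appears in the image at ``((R^T q)_x, (R^T q)_y)``;
the image frame vectors are therefore the *columns* of R.  Interpolation is
trilinear throughout and is the single source of geometric tolerance quoted
in the tests.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .core import OrientationAngles, VolumeMap

__all__ = [
    "euler_to_matrix",
    "matrix_to_euler",
    "rotate_volume",
    "project",
    "backproject_one",
    "uniform_orientations",
]


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """3x3 rotation matrix for intrinsic ZYZ Euler angles in degrees."""
    return Rotation.from_euler("ZYZ", [rot, tilt, psi], degrees=True).as_matrix()


def matrix_to_euler(matrix: np.ndarray) -> tuple:
    """Inverse of :func:`euler_to_matrix`; angles in degrees.

    At tilt = 0 or 180 (gimbal lock) only rot + psi is determined; psi is
    reported as 0 there.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        rot, tilt, psi = Rotation.from_matrix(matrix).as_euler("ZYZ", degrees=True)
    return rot % 360.0, tilt, psi % 360.0


def _matrix_xyz_to_zyx(matrix: np.ndarray) -> np.ndarray:
    # arrays are indexed (z, y, x); flip both axes of the xyz matrix
    return matrix[::-1, ::-1]


def rotate_volume(data: np.ndarray, matrix: np.ndarray, order: int = 1) -> np.ndarray:
    """Actively rotate ``data`` by ``matrix`` about the box center.

    Returns V_rot with V_rot(x) = V(R^-1 x), x relative to the center voxel.
    """
    m = _matrix_xyz_to_zyx(np.asarray(matrix, dtype=float))
    center = (np.array(data.shape) - 1) / 2.0
    # affine_transform: output[o] = input[M @ o + offset]; want M = R^-1
    minv = m.T  # rotation matrices: inverse == transpose
    offset = center - minv @ center
    return ndimage.affine_transform(
        data, minv, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=False,
    )


def project(volume: VolumeMap, angles: OrientationAngles) -> np.ndarray:
    """Line-integral projection of the rotated volume along +z.

    The returned image is the plain voxel sum along z (values in
    density x voxel units); it is linear in the volume and conserves total
    mass up to interpolation.
    """
    if volume.data.shape[0] != volume.data.shape[1] or volume.data.shape[0] != volume.data.shape[2]:
        raise ValueError("project requires a cubic volume")
    matrix = euler_to_matrix(angles.rot, angles.tilt, angles.psi)
    rotated = rotate_volume(volume.data, matrix.T)
    img = rotated.sum(axis=0)
    if angles.shift_x or angles.shift_y:
        img = ndimage.shift(img, (angles.shift_y, angles.shift_x), order=1,
                            mode="constant", cval=0.0, prefilter=False)
    return img.astype(np.float32)


def backproject_one(image: np.ndarray, angles: OrientationAngles) -> np.ndarray:
    """Adjoint of :func:`project` for a single image.

    Smears the image into a cube along +z, then rotates by the inverse of the
    projection rotation, so that ``<project(V, a), img> == <V, backproject_one(img, a)>``
    up to interpolation.
    """
    n = image.shape[0]
    if angles.shift_x or angles.shift_y:
        image = ndimage.shift(image, (-angles.shift_y, -angles.shift_x), order=1,
                              mode="constant", cval=0.0, prefilter=False)
    smear = np.broadcast_to(image, (n, n, n)).astype(np.float32)
    matrix = euler_to_matrix(angles.rot, angles.tilt, angles.psi)
    return rotate_volume(np.ascontiguousarray(smear), matrix)


def uniform_orientations(n: int, rng: np.random.Generator) -> list:
    """Draw ``n`` orientations uniformly over SO(3).

    rot, psi ~ U[0, 360); cos(tilt) ~ U[-1, 1] (area-uniform on the sphere).
    """
    rot = rng.uniform(0.0, 360.0, n)
    psi = rng.uniform(0.0, 360.0, n)
    tilt = np.degrees(np.arccos(rng.uniform(-1.0, 1.0, n)))
    return [OrientationAngles(r, t, p) for r, t, p in zip(rot, tilt, psi)]
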