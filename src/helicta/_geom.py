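"""Shared geometry and Fourier helpers.

Conventions used throughout the package:

* volume arrays are indexed ``[z, y, x]``;
* physical coordinates are right-handed ``(x, y, z)`` in Angstrom, with the
  center of voxel ``(0, 0, 0)`` at the volume origin;
* Euler angles are intrinsic ZYZ in degrees, describing the rotation that
  takes the reference into the particle:  ``R = Rz(rot) @ Ry(tilt) @ Rz(psi)``;
* interpolation is trilinear everywhere (``order=1``), the accuracy/speed
  compromise appropriate at the ~25 A resolutions targeted here.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def rot_z(angle_deg: float) -> np.ndarray:
    """Rotation matrix about +z acting on (x, y, z) column vectors."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_y(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_x(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def euler_zyz_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """Intrinsic ZYZ rotation matrix, angles in degrees."""
    return rot_z(rot) @ rot_y(tilt) @ rot_z(psi)


def matrix_to_euler_zyz(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_zyz_to_matrix`; tilt returned in [0, 180]."""
    tilt = np.rad2deg(np.arccos(np.clip(R[2, 2], -1.0, 1.0)))
    if np.sin(np.deg2rad(tilt)) > 1e-8:
        rot = np.rad2deg(np.arctan2(R[1, 2], R[0, 2]))
        psi = np.rad2deg(np.arctan2(R[2, 1], -R[2, 0]))
    else:
        # gimbal lock: fold everything into rot
        rot = np.rad2deg(np.arctan2(R[1, 0], R[0, 0]))
        psi = 0.0
        if R[2, 2] < 0:
            rot = -rot
    return float(rot), float(tilt), float(psi)


def minimal_rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Smallest rotation mapping unit vector ``v`` onto +z.

    The in-plane azimuth after the rotation is therefore fixed by the
    geometry itself (no torsion carried over), which is the package-wide
    convention for orienting filament segments.
    """
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # antiparallel: rotate 180 deg about x (any in-plane axis works)
        return rot_x(180.0)
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def volume_center(shape: tuple[int, ...]) -> np.ndarray:
    """Rotation/box center in voxel units, xyz order: ``n // 2`` per axis.

    Matches the usual single-particle convention for even boxes.
    """
    nz, ny, nx = shape
    return np.array([nx // 2, ny // 2, nz // 2], dtype=float)


def rotate_data(
    data: np.ndarray,
    R: np.ndarray,
    order: int = 1,
    center: np.ndarray | None = None,
    shift_xyz: np.ndarray | None = None,
) -> np.ndarray:
    """Apply rotation ``R`` (and optional post-shift, voxel units, xyz) to a volume.

    The object is rotated: ``out(r) = in(R^-1 (r - c - t) + c)`` with ``c`` the
    box center and ``t`` the shift.  ``data`` is indexed [z, y, x]; ``R`` acts
    on xyz column vectors.
    """
    data = np.asarray(data, dtype=float)
    c = volume_center(data.shape) if center is None else np.asarray(center, float)
    t = np.zeros(3) if shift_xyz is None else np.asarray(shift_xyz, float)
    Rinv = R.T
    # matrix acting on index vectors (z, y, x): P R^-1 P with P the xyz<->zyx flip
    M = Rinv[::-1, ::-1]
    c_zyx = c[::-1]
    t_zyx = t[::-1]
    offset = c_zyx - M @ (c_zyx + t_zyx)
    return ndimage.affine_transform(
        data, M, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=order > 1,
    )


def sample_at_points(
    data: np.ndarray, points_xyz_vox: np.ndarray, order: int = 1
) -> np.ndarray:
    """Trilinear sampling of a [z,y,x] volume at xyz voxel coordinates (N, 3)."""
    coords = points_xyz_vox[:, ::-1].T  # -> (3, N) in zyx order
    return ndimage.map_coordinates(
        np.asarray(data, float), coords, order=order, mode="constant", cval=0.0,
        prefilter=False,
    )


def freq_grids(shape: tuple[int, ...], voxel_size: float):
    """Fourier frequency coordinate grids (1/A) in zyx order for np.fft.fftn."""
    axes = [np.fft.fftfreq(n, d=voxel_size) for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def lowpass(
    data: np.ndarray, voxel_size: float, resolution: float, soft_width: float = 0.01
) -> np.ndarray:
    """Low-pass filter a 2D image or 3D volume to ``resolution`` (A).

    A cosine-edged mask of half-width ``soft_width`` (1/A) around the cutoff
    frequency suppresses ringing; used wherever the workflow calls for a
    filtered reference (e.g. the 60 A cutoff that seeds alignment).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    grids = freq_grids(data.shape, voxel_size)
    k = np.sqrt(sum(g * g for g in grids))
    kc = 1.0 / resolution
    mask = np.ones_like(k)
    edge = (k > kc - soft_width) & (k < kc + soft_width)
    mask[k >= kc + soft_width] = 0.0
    mask[edge] = 0.5 * (1.0 + np.cos(np.pi * (k[edge] - kc + soft_width) / (2 * soft_width)))
    out = np.fft.ifftn(np.fft.fftn(data) * mask).real
    return out


def normalize(img: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Zero-mean, unit-variance normalization (optionally inside a mask)."""
    if mask is not None:
        m = img[mask]
        mu, sd = float(m.mean()), float(m.std())
    else:
        mu, sd = float(img.mean()), float(img.std())
    if sd == 0:
        return img - mu
    return (img - mu) / sd


def soft_cylinder_mask(
    shape: tuple[int, int, int],
    radius_vox: float,
    soft_vox: float = 2.0,
    z_fraction: float = 1.0,
) -> np.ndarray:
    """Soft-edged cylindrical mask along z, used for scoring filament maps."""
    nz, ny, nx = shape
    cz, cy, cx = nz // 2, ny // 2, nx // 2
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    m = np.clip((radius_vox + soft_vox - r) / soft_vox, 0.0, 1.0)
    if z_fraction < 1.0:
        half = 0.5 * z_fraction * nz
        zdist = np.abs(zz - cz)
        mz = np.clip((half + soft_vox - zdist) / soft_vox, 0.0, 1.0)
        m = m * mz
    return m


def soft_sphere_mask(
    shape: tuple[int, int, int], radius_vox: float, soft_vox: float = 2.0
) -> np.ndarray:
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz) - nz // 2,
        np.arange(ny) - ny // 2,
        np.arange(nx) - nx // 2,
        indexing="ij",
    )
    r = np.sqrt(zz**2 + yy**2 + xx**2)
    return np.clip((radius_vox + soft_vox - r) / soft_vox, 0.0, 1.0)


def masked_correlation(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation of two arrays under a (soft) weight mask."""
    w = mask.ravel()
    wa = a.ravel()
    wb = b.ravel()
    wsum = w.sum()
    ma = (w * wa).sum() / wsum
    mb = (w * wb).sum() / wsum
    da, db = wa - ma, wb - mb
    num = (w * da * db).sum()
    den = np.sqrt((w * da * da).sum() * (w * db * db).sum())
    if den == 0:
        return 0.0
    return float(num / den)
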