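"""Synthetic tomogram generation with exact ground truth.

This module stands in for the cryo-ET data the workflows were designed for:
it renders filamentous densities with F-actin-like helical geometry
(default rise 27.9 A per subunit, twist -167.7 deg per subunit, the refined
values of the Lokiactin filament), globular ribosome-like particles with
optional surface blobs mimicking rRNA expansion segments, the single-axis
missing wedge of a -60..+60 deg tilt range, and additive Gaussian noise at a
configurable SNR.  Every rendered subunit and particle pose is recorded in a
:class:`GroundTruth` object, so downstream alignment, classification,
polarity voting and difference-density detection can all be scored exactly.

What is deliberately *not* modelled: electron-optical image formation (dose
weighting, detector MTF, amplitude contrast) and per-tilt CTF; an optional
single analytic 2D CTF can be enabled for projections, but it is off by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, ndimage

from ._geom import rot_z, rotate_data, minimal_rotation_to_z, volume_center
from .tables import FilamentTrace
from .volume import Volume

# Refined helical parameters of the Lokiactin filament; F-actin-like.
LOKIACTIN_RISE = 27.9       # A per subunit
LOKIACTIN_TWIST = -167.7    # deg per subunit (negative = left-handed 1-start)


@dataclass
class HelicalParams:
    """Rise (A/subunit) and twist (deg/subunit) of a 1-start helix."""

    rise: float
    twist: float

    def __post_init__(self) -> None:
        if not self.rise > 0:
            raise ValueError("rise must be positive")
        if not (-180.0 < self.twist <= 180.0):
            raise ValueError("twist must lie in (-180, 180]")


@dataclass
class AcquisitionGeometry:
    """Single-axis tilt geometry defining the missing wedge.

    ``tilt_axis`` is the in-plane rotation axis ('y' by default, or a unit
    xy-vector); the beam runs along z.  Defaults match a dose-symmetric
    -60..+60 deg acquisition at 2 deg increments.
    """

    tilt_min: float = -60.0
    tilt_max: float = 60.0
    increment: float = 2.0
    tilt_axis: str | tuple[float, float] = "y"

    def __post_init__(self) -> None:
        if not self.tilt_min < 0 < self.tilt_max:
            raise ValueError("tilt range must straddle 0")
        if abs(self.tilt_min) > 90 or abs(self.tilt_max) > 90:
            raise ValueError("|tilt| must be <= 90 deg")

    def axis_vector(self) -> np.ndarray:
        if isinstance(self.tilt_axis, str):
            if self.tilt_axis == "y":
                return np.array([0.0, 1.0])
            if self.tilt_axis == "x":
                return np.array([1.0, 0.0])
            raise ValueError("tilt_axis string must be 'x' or 'y'")
        v = np.asarray(self.tilt_axis, float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("tilt_axis vector must be non-zero")
        return v / n


@dataclass
class GroundTruth:
    """Exact bookkeeping of everything the simulator placed in a volume."""

    subunits: pd.DataFrame = field(default_factory=pd.DataFrame)
    particles: pd.DataFrame = field(default_factory=pd.DataFrame)
    traces: list[FilamentTrace] = field(default_factory=list)
    filament_polarity: dict = field(default_factory=dict)  # filament_id -> +-1
    helical: HelicalParams | None = None
    noise_sigma: float = 0.0
    geometry: AcquisitionGeometry | None = None

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            subunits=pd.concat([self.subunits, other.subunits], ignore_index=True),
            particles=pd.concat([self.particles, other.particles], ignore_index=True),
            traces=self.traces + other.traces,
            filament_polarity={**self.filament_polarity, **other.filament_polarity},
            helical=self.helical or other.helical,
            noise_sigma=max(self.noise_sigma, other.noise_sigma),
            geometry=self.geometry or other.geometry,
        )


# ---------------------------------------------------------------------------
# subunit models
# ---------------------------------------------------------------------------

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def make_subunit_model(
    kind: str, diameter: float, voxel_size: float, box: int | None = None
) -> Volume:
    """Pseudo-atomic stand-in for a protein subunit.

    Parameters
    ----------
    kind:
        ``gaussian_blob`` — isotropic Gaussian with FWHM = diameter;
        ``two_lobe`` — a large and a small Gaussian displaced along the
        subunit z-axis (axially asymmetric, so filament polarity is encoded);
        ``sphere_shell`` — density peaked on a spherical shell of the given
        diameter, ~0 at the center.
    diameter:
        Characteristic size in Angstrom; must fit inside the box.
    """
    if box is None:
        box = int(np.ceil(1.6 * diameter / voxel_size)) | 1  # odd box, voxel-centered
    if diameter >= box * voxel_size:
        raise ValueError(
            f"diameter {diameter} A does not fit in a {box}-voxel box at "
            f"{voxel_size} A/voxel"
        )
    c = box // 2
    zz, yy, xx = np.meshgrid(*(np.arange(box) - c,) * 3, indexing="ij")
    zz, yy, xx = (a * voxel_size for a in (zz, yy, xx))
    r2 = xx**2 + yy**2 + zz**2
    if kind == "gaussian_blob":
        sigma = diameter * _FWHM_TO_SIGMA
        data = np.exp(-0.5 * r2 / sigma**2)
    elif kind == "two_lobe":
        s_big = 0.45 * diameter * _FWHM_TO_SIGMA
        s_small = 0.33 * diameter * _FWHM_TO_SIGMA
        dz = 0.26 * diameter
        big = np.exp(-0.5 * (xx**2 + yy**2 + (zz - dz) ** 2) / s_big**2)
        small = 0.65 * np.exp(-0.5 * (xx**2 + yy**2 + (zz + dz) ** 2) / s_small**2)
        data = big + small
    elif kind == "sphere_shell":
        radius = diameter / 2.0
        shell_sigma = max(0.12 * diameter, voxel_size)
        data = np.exp(-0.5 * (np.sqrt(r2) - radius) ** 2 / shell_sigma**2)
    else:
        raise ValueError(f"unknown subunit kind {kind!r}")
    data = data / data.max()
    return Volume(data, voxel_size)


# ---------------------------------------------------------------------------
# filament rendering
# ---------------------------------------------------------------------------


def _trace_spline(points: np.ndarray):
    """Arc-length parametrized interpolant of a polyline (cubic if possible)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    k = min(3, len(points) - 1)
    spl = interpolate.make_interp_spline(t, points, k=k)
    # re-parametrize by true arc length on a dense sampling
    tt = np.linspace(0, t[-1], max(4 * len(points), 200))
    dense = spl(tt)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    return spl, tt, arc


def trace_arc_length(trace: FilamentTrace) -> float:
    _, _, arc = _trace_spline(trace.control_points)
    return float(arc[-1])


def _frames_along(spl, tt, arc, s_values: np.ndarray):
    """Positions, tangents and parallel-transported normals at arc lengths."""
    t_of_s = np.interp(s_values, arc, tt)
    pos = spl(t_of_s)
    tang = spl.derivative()(t_of_s)
    tang = tang / np.linalg.norm(tang, axis=1, keepdims=True)
    # parallel transport of an initial normal along the curve
    n1 = np.empty_like(tang)
    t0 = tang[0]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n = np.cross(t0, ref)
    n /= np.linalg.norm(n)
    n1[0] = n
    for i in range(1, len(tang)):
        a, b = tang[i - 1], tang[i]
        c = np.cross(a, b)
        s = np.linalg.norm(c)
        if s < 1e-12:
            n1[i] = n1[i - 1]
            continue
        axis = c / s
        ang = np.arctan2(s, np.dot(a, b))
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        n1[i] = R @ n1[i - 1]
        n1[i] /= np.linalg.norm(n1[i])
    n2 = np.cross(tang, n1)
    return pos, tang, n1, n2


def _paste_subunit(
    target: np.ndarray,
    subunit: Volume,
    R: np.ndarray,
    center_xyz_vox: np.ndarray,
    voxel_size: float,
) -> None:
    """Add a rotated copy of the subunit density at a (fractional) position."""
    sub = subunit.data
    scale = subunit.voxel_size / voxel_size
    half = 0.5 * max(sub.shape) * scale + 2
    lo = np.floor(center_xyz_vox - half).astype(int)
    hi = np.ceil(center_xyz_vox + half).astype(int) + 1
    nz, ny, nx = target.shape
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, [nx, ny, nz])
    if np.any(hi <= lo):
        return
    xs = np.arange(lo[0], hi[0])
    ys = np.arange(lo[1], hi[1])
    zs = np.arange(lo[2], hi[2])
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    rel = np.stack(
        [xx - center_xyz_vox[0], yy - center_xyz_vox[1], zz - center_xyz_vox[2]]
    ).reshape(3, -1)
    sub_center = volume_center(sub.shape)
    src = (R.T @ rel) / scale + sub_center[:, None]  # xyz voxel coords in subunit
    vals = ndimage.map_coordinates(
        sub, src[::-1], order=1, mode="constant", cval=0.0, prefilter=False
    )
    target[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]] += vals.reshape(zz.shape)


def render_filament(
    trace: FilamentTrace,
    params: HelicalParams,
    subunit: Volume,
    volume_shape: tuple[int, int, int],
    voxel_size: float,
    two_strands: bool = True,
    strand_radius: float = 15.0,
    azimuth0: float = 0.0,
    polarity: int = 1,
    origin: np.ndarray | None = None,
    out: Volume | None = None,
) -> tuple[Volume, GroundTruth]:
    """Render a helical filament along a (possibly curved) trace.

    Subunit k sits at arc length ``k * rise`` with azimuth
    ``azimuth0 + k * twist`` about the local axis, displaced ``strand_radius``
    (A) radially off the centerline; with ``two_strands`` a second strand is
    added at +180 deg azimuth (2-start geometry).  Each subunit's local frame
    twists with its azimuth and its z-axis follows the filament tangent
    (flipped when ``polarity`` is -1), so both the helical hand and the
    filament polarity are encoded in the density.  Local frames are parallel
    transported along the curve to avoid torsion artifacts.

    Returns the volume plus a :class:`GroundTruth` listing every subunit pose.
    """
    if polarity not in (+1, -1):
        raise ValueError("polarity must be +1 or -1")
    vol = (
        out
        if out is not None
        else Volume(np.zeros(volume_shape), voxel_size, origin if origin is not None else np.zeros(3))
    )
    L = trace_arc_length(trace)
    gt = GroundTruth(helical=params, traces=[trace], filament_polarity={trace.filament_id: polarity})
    if L < params.rise:
        warnings.warn(
            f"trace {trace.filament_id} shorter than one rise ({L:.1f} < {params.rise} A); "
            "nothing rendered"
        )
        return vol, gt
    spl, tt, arc = _trace_spline(trace.control_points)
    n_sub = int(np.floor(L / params.rise + 1e-9)) + 1
    s_vals = np.arange(n_sub) * params.rise
    pos, tang, n1, n2 = _frames_along(spl, tt, arc, s_vals)
    strands = (0.0, 180.0) if two_strands else (0.0,)
    from ._geom import rot_x

    rows = []
    for k in range(n_sub):
        az_base = azimuth0 + k * params.twist
        for strand_idx, offs in enumerate(strands):
            az = (az_base + offs) % 360.0
            radial = np.cos(np.deg2rad(az)) * n1[k] + np.sin(np.deg2rad(az)) * n2[k]
            center = pos[k] + strand_radius * radial
            # subunit pose: z along the tangent, twisted about it by the
            # azimuth, built from the same parallel-transported frame
            # (n1, n2, t) as the positions.  Referencing poses to any other
            # zero-azimuth (e.g. a minimal-rotation frame) would rotate the
            # subunits relative to the position lattice by an angle that
            # depends on the filament direction.  For polarity -1 each pose
            # is composed with a local Ry(180) and a mirrored pose azimuth,
            # which makes the -1 filament exactly the in-plane 180 deg flip
            # of the +1 filament; simply pointing the subunit axis down
            # would wind the orientations with the wrong handedness.
            R_frame = np.column_stack([n1[k], n2[k], tang[k]])
            if polarity == 1:
                R = R_frame @ rot_z(az)
            else:
                R = R_frame @ rot_x(180.0) @ rot_z(-az)
            cvox = (center - vol.origin) / voxel_size
            _paste_subunit(vol.data, subunit, R, cvox, voxel_size)
            rows.append(
                dict(
                    filament_id=trace.filament_id,
                    subunit_index=k,
                    strand=strand_idx,
                    x=center[0],
                    y=center[1],
                    z=center[2],
                    azimuth=az,
                    arc_position=s_vals[k],
                    tangent_x=tang[k][0],
                    tangent_y=tang[k][1],
                    tangent_z=tang[k][2],
                    polarity=polarity,
                )
            )
    gt.subunits = pd.DataFrame(rows)
    return vol, gt


# ---------------------------------------------------------------------------
# particle fields
# ---------------------------------------------------------------------------


def _random_rotation_matrices(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotations via quaternions (Shoemake)."""
    u1, u2, u3 = rng.random((3, n))
    q = np.stack(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ],
        axis=1,
    )
    w, x, y, z = q[:, 3], q[:, 0], q[:, 1], q[:, 2]
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


class PlacementError(RuntimeError):
    """Could not place the requested number of particles."""


def scatter_particles(
    volume_shape: tuple[int, int, int],
    voxel_size: float,
    n: int,
    species_models: dict[str, Volume],
    min_distance: float,
    seed: int,
    margin: float | None = None,
    max_retries: int = 2000,
) -> tuple[Volume, GroundTruth]:
    """Scatter randomly rotated particles with non-overlapping centers.

    Species labels cycle through ``species_models`` in a seeded random order
    (balanced for n divisible by the number of species).  Raises
    :class:`PlacementError` (reporting the achieved count) if ``n`` centers
    respecting ``min_distance`` cannot be found within the retry budget.
    """
    if n < 0 or min_distance < 0:
        raise ValueError("n and min_distance must be non-negative")
    rng = np.random.default_rng(seed)
    vol = Volume(np.zeros(volume_shape), voxel_size)
    gt = GroundTruth()
    if n == 0:
        return vol, gt
    labels = list(species_models)
    if margin is None:
        margin = 0.5 * max(
            max(m.data.shape) * m.voxel_size for m in species_models.values()
        )
    extent = vol.physical_extent()
    lo = np.full(3, margin)
    hi = extent - margin
    if np.any(hi <= lo):
        raise ValueError("volume too small for the particle margin")
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_retries * n:
            raise PlacementError(
                f"placed only {len(centers)} of {n} particles at "
                f"min_distance {min_distance} A"
            )
        c = lo + rng.random(3) * (hi - lo)
        if all(np.linalg.norm(c - p) >= min_distance for p in centers):
            centers.append(c)
    Rs = _random_rotation_matrices(n, rng)
    order = rng.permutation(n)
    rows = []
    for i, (c, R) in enumerate(zip(centers, Rs)):
        label = labels[order[i] % len(labels)]
        _paste_subunit(vol.data, species_models[label], R, c / voxel_size, voxel_size)
        from ._geom import matrix_to_euler_zyz

        rot, tilt, psi = matrix_to_euler_zyz(R)
        rows.append(
            dict(
                particle_id=i, x=c[0], y=c[1], z=c[2],
                euler_rot=rot, euler_tilt=tilt, euler_psi=psi, species=label,
            )
        )
    gt.particles = pd.DataFrame(rows)
    return vol, gt


# ---------------------------------------------------------------------------
# missing wedge and noise
# ---------------------------------------------------------------------------


def missing_wedge_mask(
    shape: tuple[int, int, int], geometry: AcquisitionGeometry
) -> np.ndarray:
    """Boolean Fourier mask: True where a coefficient is sampled.

    A coefficient k is sampled if some tilt angle theta in the acquisition
    range puts it on a central section, i.e. the plane-normal condition
    ``k_u sin(theta) + k_z cos(theta) = 0`` has a solution, where u is the
    in-plane direction perpendicular to the tilt axis.  For a symmetric
    +-60 deg range this zeroes a wedge of half-angle 30 deg about the k_z
    axis — one third of Fourier space.
    """
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    ky = np.fft.fftfreq(ny)[None, :, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    a = geometry.axis_vector()
    # in-plane direction that tilts into z: u = axis x z_hat (up to sign)
    ku = a[1] * kx - a[0] * ky
    theta = np.rad2deg(np.arctan2(-kz, ku))  # tilt solving the section equation
    theta = np.broadcast_to(theta, (nz, ny, nx)).copy()
    # theta and theta+-180 describe the same central section
    thetawrapped = (theta + 90.0) % 180.0 - 90.0
    sampled = (thetawrapped >= geometry.tilt_min - 1e-9) & (
        thetawrapped <= geometry.tilt_max + 1e-9
    )
    sampled[0, :, :] |= np.abs(np.broadcast_to(ku, (1, ny, nx))[0]) < 1e-12
    return sampled


def sampled_directions(k_xyz: np.ndarray, geometry: AcquisitionGeometry) -> np.ndarray:
    """Whether Fourier directions (N, 3, xyz, tomogram frame) are sampled.

    Used to carry the wedge footprint through segment rotations: the mask of
    a rotated subvolume is this predicate evaluated on back-rotated
    frequency vectors.
    """
    a = geometry.axis_vector()
    ku = a[1] * k_xyz[:, 0] - a[0] * k_xyz[:, 1]
    kz = k_xyz[:, 2]
    theta = np.rad2deg(np.arctan2(-kz, ku))
    wrapped = (theta + 90.0) % 180.0 - 90.0
    ok = (wrapped >= geometry.tilt_min - 1e-9) & (wrapped <= geometry.tilt_max + 1e-9)
    ok |= (np.abs(ku) < 1e-12) & (np.abs(kz) < 1e-12)
    return ok


def missing_wedge_fraction(
    shape: tuple[int, int, int], geometry: AcquisitionGeometry
) -> float:
    """Fraction of Fourier space lost to the wedge, as a solid-angle fraction.

    Counted over the Nyquist-resolved region (|k| <= Nyquist in the plane
    perpendicular to the tilt axis), where the angular fraction is the
    meaningful quantity: a +-60 deg tilt range loses a wedge of half-angle
    30 deg on both sides of the beam axis — one third.  The square corners of
    the discrete FFT grid beyond Nyquist are excluded because their angular
    coverage is an artifact of the grid, not of the acquisition.
    """
    mask = missing_wedge_mask(shape, geometry)
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    ky = np.fft.fftfreq(ny)[None, :, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    a = geometry.axis_vector()
    ku = a[1] * kx - a[0] * ky
    in_disc = np.broadcast_to(np.sqrt(ku**2 + kz**2), shape) <= 0.5
    return float(1.0 - mask[in_disc].mean())


def apply_missing_wedge(volume: Volume, geometry: AcquisitionGeometry) -> Volume:
    """Zero the Fourier coefficients lost to the limited tilt range."""
    mask = missing_wedge_mask(volume.shape, geometry)
    F = np.fft.fftn(volume.data)
    F[~mask] = 0.0
    return volume.with_data(np.fft.ifftn(F).real)


def add_noise(
    volume: Volume,
    snr: float,
    seed: int,
    signal_mask: np.ndarray | None = None,
) -> Volume:
    """Add white Gaussian noise at a given SNR.

    SNR is defined as signal variance over noise variance *within the signal
    support mask* (by default, voxels above 10% of the peak absolute density).
    This convention matters: measuring over the whole, mostly empty box would
    report a much lower apparent SNR for the same noise level.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    data = volume.data
    if signal_mask is None:
        signal_mask = np.abs(data) > 0.1 * np.abs(data).max()
    if not signal_mask.any():
        raise ValueError("empty signal support: SNR is undefined")
    sig_var = float(data[signal_mask].var())
    sigma = np.sqrt(sig_var / snr)
    rng = np.random.default_rng(seed)
    return volume.with_data(data + rng.normal(0.0, sigma, size=data.shape))


def ctf_2d(
    shape: tuple[int, int],
    pixel_size: float,
    defocus: float,
    voltage_kv: float = 300.0,
    cs_mm: float = 2.7,
    amplitude_contrast: float = 0.07,
) -> np.ndarray:
    """Analytic 2D contrast transfer function (unshifted fft2 layout).

    ``defocus`` is in Angstrom, positive = underfocus.  Standard weak-phase
    model: CTF(k) = -[sqrt(1-A^2) sin(chi) + A cos(chi)] with
    chi = pi lambda df k^2 - (pi/2) Cs lambda^3 k^4.
    """
    if defocus <= 0:
        raise ValueError("defocus must be positive (underfocus, Angstrom)")
    # relativistic electron wavelength in Angstrom
    v = voltage_kv * 1e3
    lam = 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))
    cs = cs_mm * 1e7  # mm -> A
    ki = np.fft.fftfreq(shape[0], d=pixel_size)
    kj = np.fft.fftfreq(shape[1], d=pixel_size)
    k2 = ki[:, None] ** 2 + kj[None, :] ** 2
    chi = np.pi * lam * defocus * k2 - 0.5 * np.pi * cs * lam**3 * k2**2
    A = amplitude_contrast
    return -(np.sqrt(1.0 - A**2) * np.sin(chi) + A * np.cos(chi))


def apply_ctf(
    image: np.ndarray,
    pixel_size: float,
    defocus: float,
    **ctf_kwargs,
) -> np.ndarray:
    """Multiply a 2D projection image by an analytic CTF (optional, off by
    default everywhere in the package — per-tilt CTF handling of real data
    is out of scope, but synthetic projections can carry a single CTF)."""
    ctf = ctf_2d(image.shape, pixel_size, defocus, **ctf_kwargs)
    return np.fft.ifft2(np.fft.fft2(image) * ctf).real


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def lokiactin_subunit(voxel_size: float, diameter: float = 50.0) -> Volume:
    """Default actin-like subunit: a chiral, polar two-lobe model.

    A large lobe sits on the subunit axis toward +z and a smaller lobe below
    it, displaced tangentially off-axis (mimicking the uneven subdomain mass
    of an actin fold).  The tangential offset matters: a 2-start filament
    built from *azimuthally symmetric* subunits is almost exactly symmetric
    under an in-plane 180 deg flip (the subunit position lattice maps onto
    itself), which would make filament polarity fundamentally undetectable in
    projections.  The off-axis lobe breaks that degeneracy.
    """
    d = diameter
    box = int(np.ceil(1.8 * d / voxel_size)) | 1
    c = box // 2
    zz, yy, xx = np.meshgrid(*(np.arange(box) - c,) * 3, indexing="ij")
    zz, yy, xx = (a * voxel_size for a in (zz, yy, xx))
    s_big = 0.45 * d * _FWHM_TO_SIGMA
    s_small = 0.33 * d * _FWHM_TO_SIGMA
    dz = 0.26 * d
    ty = 0.35 * d
    data = np.exp(-0.5 * (xx**2 + yy**2 + (zz - dz) ** 2) / s_big**2) + 0.5 * np.exp(
        -0.5 * (xx**2 + (yy - ty) ** 2 + (zz + dz) ** 2) / s_small**2
    )
    return Volume(data / data.max(), voxel_size)


def make_filament_reference(
    box: int,
    voxel_size: float,
    params: HelicalParams | None = None,
    subunit: Volume | None = None,
    two_strands: bool = True,
) -> Volume:
    """Render a centered straight filament for use as an alignment reference.

    With F-actin-like default parameters (rise 27.5 A, twist -166.7 deg)
    this is the synthetic analogue of seeding the analysis with a published
    actin map: close enough in geometry to bootstrap azimuth assignment, and
    always low-pass filtered (60 A) by the alignment stage so its fine
    detail cannot bias the result.
    """
    if params is None:
        params = HelicalParams(27.5, -166.7)
    if subunit is None:
        subunit = lokiactin_subunit(voxel_size)
    c = box // 2 * voxel_size
    L = box * voxel_size
    trace = FilamentTrace(
        filament_id=-1,
        control_points=np.array([[c, c, c - L], [c, c, c + L]]),
    )
    vol, _ = render_filament(
        trace, params, subunit, (box, box, box), voxel_size, two_strands=two_strands
    )
    return vol


def lokiactin_filament_dataset(
    n_filaments: int,
    snr: float,
    seed: int,
    voxel_size: float = 5.36,
    tomo_shape: tuple[int, int, int] = (80, 112, 112),
    filament_length: float = 420.0,
    params: HelicalParams | None = None,
    geometry: AcquisitionGeometry | None = None,
    max_out_of_plane: float = 8.0,
    randomize_polarity: bool = True,
):
    """The study-condition filament simulation: one filament per tomogram.

    Each filament is a straight trace through the tomogram center with a
    random in-plane direction and a small out-of-plane tilt (filaments in
    lamella tomograms lie nearly in the xy plane), random helical phase and
    (optionally) random polarity.  The volume is wedge-filtered (+-60 deg
    single-axis by default) and noise is added at the requested SNR.

    Returns a list of ``(tomogram, trace, ground_truth)`` triples.
    """
    if params is None:
        params = HelicalParams(LOKIACTIN_RISE, LOKIACTIN_TWIST)
    if geometry is None:
        geometry = AcquisitionGeometry()
    rng = np.random.default_rng(seed)
    subunit = lokiactin_subunit(voxel_size)
    out = []
    for i in range(n_filaments):
        nz, ny, nx = tomo_shape
        center = 0.5 * np.array([nx, ny, nz]) * voxel_size
        phi = rng.uniform(0, 360)
        oop = rng.uniform(-max_out_of_plane, max_out_of_plane)
        d = np.array(
            [
                np.cos(np.deg2rad(phi)) * np.cos(np.deg2rad(oop)),
                np.sin(np.deg2rad(phi)) * np.cos(np.deg2rad(oop)),
                np.sin(np.deg2rad(oop)),
            ]
        )
        half = 0.5 * filament_length
        trace = FilamentTrace(
            filament_id=i,
            control_points=np.array([center - half * d, center + half * d]),
            source_volume_id=i,
        )
        polarity = int(rng.choice([1, -1])) if randomize_polarity else 1
        vol, gt = render_filament(
            trace,
            params,
            subunit,
            tomo_shape,
            voxel_size,
            two_strands=True,
            azimuth0=float(rng.uniform(0, 360)),
            polarity=polarity,
        )
        vol = apply_missing_wedge(vol, geometry)
        vol = add_noise(vol, snr, seed=int(rng.integers(2**31)))
        gt.geometry = geometry
        out.append((vol, trace, gt))
    return out


def ribosome_field(
    n: int,
    snr: float,
    seed: int,
    voxel_size: float = 9.02,
    volume_shape: tuple[int, int, int] = (96, 192, 192),
    with_expansion_blob: bool = True,
    geometry: AcquisitionGeometry | None = None,
):
    """A field of 70S-ribosome-like particles, half with a surface blob.

    The blob mimics an rRNA expansion segment: extra density on the particle
    surface that survives averaging and shows up in a difference map.
    """
    species = {"plain": ribosome_model(voxel_size, expansion_blob=False)}
    if with_expansion_blob:
        species["expanded"] = ribosome_model(voxel_size, expansion_blob=True)
    vol, gt = scatter_particles(
        volume_shape, voxel_size, n, species, min_distance=280.0, seed=seed
    )
    if geometry is not None:
        vol = apply_missing_wedge(vol, geometry)
        gt.geometry = geometry
    if snr < np.inf and n > 0:
        vol = add_noise(vol, snr, seed=seed + 1)
    return vol, gt


def ribosome_model(
    voxel_size: float,
    diameter: float = 250.0,
    expansion_blob: bool = False,
    blob_diameter: float = 70.0,
) -> Volume:
    """Globular 70S-like particle: a lumpy sphere, optionally with a surface
    blob standing in for an oversized rRNA expansion segment."""
    box = int(np.ceil(1.5 * diameter / voxel_size)) | 1
    c = box // 2
    zz, yy, xx = np.meshgrid(*(np.arange(box) - c,) * 3, indexing="ij")
    zz, yy, xx = (a * voxel_size for a in (zz, yy, xx))
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    body = 1.0 / (1.0 + np.exp((r - diameter / 2) / (0.05 * diameter)))
    # internal lumps break spherical symmetry so orientations are well defined
    lump_centers = np.array(
        [[0.25, 0.0, 0.1], [-0.2, 0.18, -0.05], [0.0, -0.25, 0.12]]
    ) * diameter
    s = 0.30 * diameter * _FWHM_TO_SIGMA
    for lx, ly, lz in lump_centers:
        body += 0.8 * np.exp(
            -0.5 * ((xx - lx) ** 2 + (yy - ly) ** 2 + (zz - lz) ** 2) / s**2
        )
    if expansion_blob:
        # prominent surface density at the +z pole, mimicking a supersized
        # rRNA expansion segment: strong enough to survive averaging and
        # stand out of a difference map at the default 3-sigma threshold
        bc = np.array([0.0, 0.0, 0.55]) * diameter
        sb = blob_diameter * _FWHM_TO_SIGMA
        body += 1.8 * np.exp(
            -0.5 * ((xx - bc[0]) ** 2 + (yy - bc[1]) ** 2 + (zz - bc[2]) ** 2) / sb**2
        )
    return Volume(body / body.max(), voxel_size)
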