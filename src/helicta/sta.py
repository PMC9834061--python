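"""Generic sub-tomogram averaging, classification and difference mapping.

The ribosome-identification workflow re-implemented on synthetic particles:
reference-based 3D alignment on a hierarchical angular grid with
missing-wedge-aware scores, expectation–maximization-style classification,
coverage-weighted averaging, rigid-body fitting of a reference into an
average, and difference-density detection of additional features such as
rRNA expansion-segment mimics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._geom import (
    euler_zyz_to_matrix,
    matrix_to_euler_zyz,
    rotate_data,
    soft_sphere_mask,
)
from .simulate import AcquisitionGeometry, missing_wedge_mask
from .tables import ParticleTable
from .volume import Volume


class NoFitError(RuntimeError):
    """Rigid-body fitting found no correlation peak above the floor."""


@dataclass
class AngularSearch:
    """Hierarchical Euler-grid settings for 3D alignment (degrees, Angstrom)."""

    coarse_step: float = 30.0
    refine_levels: int = 2
    max_shift: float = 20.0


@dataclass
class Blob:
    centroid_xyz: np.ndarray  # Angstrom
    volume: float             # Angstrom^3
    peak_density: float
    n_voxels: int
    label: str = ""


@dataclass
class BlobReport:
    """Difference-density detections against a fitted reference."""

    blobs: list[Blob]
    sigma_threshold: float
    min_blob_volume: float
    reference_correlation: float

    def __len__(self) -> int:
        return len(self.blobs)


@dataclass
class ClassifyResult:
    assignments: np.ndarray
    averages: list[Volume]
    populations: np.ndarray
    scores: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _euler_grid(step: float) -> np.ndarray:
    """(N, 3) ZYZ Euler grid covering SO(3) at roughly ``step`` degrees."""
    rots = np.arange(0.0, 360.0, step)
    tilts = np.arange(0.0, 180.0 + 1e-9, step)
    psis = np.arange(0.0, 360.0, step)
    out = []
    for t in tilts:
        # thin the azimuth ring near the poles where rot and psi degenerate
        n_rot = max(1, int(round(len(rots) * max(np.sin(np.deg2rad(t)), 1e-3))))
        for r in rots[:: max(1, len(rots) // n_rot)]:
            for p in psis:
                out.append((r, t, p))
    return np.array(out)


def _local_offsets(step: float) -> np.ndarray:
    d = np.array([-step, 0.0, step])
    g = np.stack(np.meshgrid(d, d, d, indexing="ij"), axis=-1).reshape(-1, 3)
    return g


def _score_rotation(
    Fp: np.ndarray,
    reference: Volume,
    R: np.ndarray,
    wedge: np.ndarray | None,
    max_shift_vox: int,
    p_norm: float,
):
    """Wedge-masked NCC of a particle against a rotated reference, with shifts."""
    rot_ref = rotate_data(reference.data, R)
    Fr = np.fft.fftn(rot_ref - rot_ref.mean())
    if wedge is not None:
        Fr = Fr * wedge
    r_norm = np.sqrt(max(float((np.abs(Fr) ** 2).sum()), 1e-30))
    cc = np.fft.fftshift(np.fft.ifftn(Fp * np.conj(Fr)).real)
    n = cc.shape[0]
    c = n // 2
    win = cc[
        c - max_shift_vox:c + max_shift_vox + 1,
        c - max_shift_vox:c + max_shift_vox + 1,
        c - max_shift_vox:c + max_shift_vox + 1,
    ]
    k = int(np.argmax(win))
    iz, iy, ix = np.unravel_index(k, win.shape)
    score = float(win[iz, iy, ix]) * cc.size / (p_norm * r_norm)
    shift_vox = np.array([ix, iy, iz], float) - max_shift_vox  # xyz
    return score, shift_vox


def align_subtomograms(
    particles: list[Volume],
    reference: Volume,
    geometry: AcquisitionGeometry | None = None,
    search: AngularSearch | None = None,
    lowpass_resolution: float | None = 60.0,
    priors: np.ndarray | None = None,
) -> ParticleTable:
    """Find per-particle Euler angles and shifts against a reference.

    A coarse global ZYZ grid is scored first (skipped when ``priors`` —
    (N, 3) Euler triplets — are given), then refined locally by halving the
    angular step ``search.refine_levels`` times.  Scores are normalized
    cross-correlations computed over the sampled Fourier region when
    ``geometry`` provides the missing wedge.  The reference is low-pass
    filtered before use; the rotation convention is intrinsic ZYZ taking the
    reference into the particle.
    """
    if search is None:
        search = AngularSearch()
    if not particles:
        return ParticleTable(pd.DataFrame(columns=[
            "particle_id", "center_x", "center_y", "center_z",
            "euler_rot", "euler_tilt", "euler_psi", "score",
        ]))
    from ._geom import lowpass as _lp

    ref = reference
    if lowpass_resolution:
        ref = ref.with_data(_lp(ref.data, ref.voxel_size, lowpass_resolution))
    vox = particles[0].voxel_size
    shape = particles[0].shape
    wedge = None
    if geometry is not None:
        wedge = missing_wedge_mask(shape, geometry).astype(float)
        wedge[0, 0, 0] = 0.0
    max_shift_vox = max(1, int(round(search.max_shift / vox)))
    coarse = _euler_grid(search.coarse_step)
    rows = []
    for i, p in enumerate(particles):
        data = p.data
        if lowpass_resolution:
            data = _lp(data, vox, lowpass_resolution)
        Fp = np.fft.fftn(data - data.mean())
        if wedge is not None:
            Fp = Fp * wedge
        p_norm = np.sqrt(max(float((np.abs(Fp) ** 2).sum()), 1e-30))
        if priors is not None:
            best = (-np.inf, np.asarray(priors[i], float), np.zeros(3))
        else:
            best = (-np.inf, np.zeros(3), np.zeros(3))
            for eul in coarse:
                R = euler_zyz_to_matrix(*eul)
                s, sh = _score_rotation(Fp, ref, R, wedge, max_shift_vox, p_norm)
                if s > best[0]:
                    best = (s, eul, sh)
        step = search.coarse_step / 2.0
        for _ in range(search.refine_levels):
            center_eul = best[1]
            for off in _local_offsets(step):
                eul = center_eul + off
                R = euler_zyz_to_matrix(*eul)
                s, sh = _score_rotation(Fp, ref, R, wedge, max_shift_vox, p_norm)
                if s > best[0]:
                    best = (s, eul, sh)
            step /= 2.0
        score, eul, shift_vox = best
        R = euler_zyz_to_matrix(*eul)
        rot, tilt, psi = matrix_to_euler_zyz(R)
        rows.append(
            dict(
                particle_id=i,
                center_x=shift_vox[0] * vox,
                center_y=shift_vox[1] * vox,
                center_z=shift_vox[2] * vox,
                euler_rot=rot,
                euler_tilt=tilt,
                euler_psi=psi,
                score=score,
            )
        )
    return ParticleTable(pd.DataFrame(rows))


def _unpose(particle: Volume, eulers, shift_xyz_A=None) -> np.ndarray:
    """Map a posed particle back into the reference frame."""
    R = euler_zyz_to_matrix(*eulers)
    vox = particle.voxel_size
    t = np.zeros(3) if shift_xyz_A is None else np.asarray(shift_xyz_A) / vox
    return rotate_data(particle.data, R.T, shift_xyz=-(R.T @ t))


def average_subtomograms(
    particles: list[Volume],
    table: ParticleTable,
    geometry: AcquisitionGeometry | None = None,
    coverage_floor: float = 0.5,
) -> Volume:
    """Average aligned particles with per-voxel wedge-coverage weighting.

    Each particle is rotated/shifted into the reference frame; with
    ``geometry`` the per-particle missing-wedge masks are rotated along and
    accumulated into a Fourier coverage map, and the summed transform is
    divided by the coverage (floored at ``coverage_floor`` so empty regions
    do not blow up).  Without geometry this reduces to a plain mean.
    """
    if not particles:
        raise ValueError("cannot average zero particles")
    if len(particles) != len(table):
        raise ValueError("particle list and table lengths differ")
    vox = particles[0].voxel_size
    eulers = table.eulers()
    shifts = table.centers()
    if geometry is None:
        acc = np.zeros(particles[0].shape)
        for p, e, t in zip(particles, eulers, shifts):
            acc += _unpose(p, e, t)
        return Volume(acc / len(particles), vox)
    wedge = missing_wedge_mask(particles[0].shape, geometry).astype(float)
    Facc = np.zeros(particles[0].shape, complex)
    cov = np.zeros(particles[0].shape)
    for p, e, t in zip(particles, eulers, shifts):
        un = _unpose(p, e, t)
        Facc += np.fft.fftn(un)
        R = euler_zyz_to_matrix(*e)
        # the wedge mask lives in the tomogram frame; unposing rotates it
        # too (rotate in the centered frame, then back — ifftshift, which
        # differs from fftshift for odd boxes)
        cov += np.abs(np.fft.ifftshift(rotate_data(np.fft.fftshift(wedge), R.T)))
    F = Facc / np.maximum(cov, coverage_floor)
    return Volume(np.fft.ifftn(F).real, vox)


def classify_subtomograms(
    particles: list[Volume],
    k: int,
    references: list[Volume] | None = None,
    n_iter: int = 8,
    seed: int = 0,
    table: ParticleTable | None = None,
    geometry: AcquisitionGeometry | None = None,
    mask_radius_fraction: float = 0.45,
    lowpass_resolution: float | None = 60.0,
) -> ClassifyResult:
    """Reference-based (or de novo) classification of aligned particles.

    Expectation–maximization-style alternation of correlation assignment and
    class averaging.  When ``table`` is given, particles are first mapped
    into the common reference frame using its poses ('classification without
    angular sampling').  Initial class averages come from ``references`` or
    from a seeded random split.  Assignment correlations are computed on
    60 A low-pass filtered copies by default: the differences that matter at
    this scale are large (a surface blob, a missing domain) and the filter
    keeps per-particle noise from dominating the metric.
    """
    n = len(particles)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of particles ({n})")
    vox = particles[0].voxel_size
    if table is not None:
        eulers = table.eulers()
        shifts = table.centers()
        vols = [_unpose(p, e, t) for p, e, t in zip(particles, eulers, shifts)]
    else:
        vols = [p.data for p in particles]
    vols_raw = vols
    if lowpass_resolution:
        from ._geom import lowpass as _lp

        vols = [_lp(v, vox, lowpass_resolution) for v in vols]
    shape = vols[0].shape
    rng = np.random.default_rng(seed)
    if geometry is not None:
        # wedge-aware metric: each particle is compared only over its own
        # sampled Fourier region (the rotated wedge), and class means are
        # coverage-weighted.  Without this, the dominant between-particle
        # variance is the wedge orientation itself and the classes split on
        # it instead of on structure.
        wedge = np.fft.fftshift(missing_wedge_mask(shape, geometry).astype(float))
        grids = np.meshgrid(*[np.fft.fftfreq(s, d=vox) for s in shape], indexing="ij")
        kk = np.sqrt(sum(g * g for g in grids))
        low_sel = (kk < (1.0 / lowpass_resolution if lowpass_resolution else np.inf)) & (kk > 0)
        Rs = [
            euler_zyz_to_matrix(*table.eulers()[i]) if table is not None else np.eye(3)
            for i in range(n)
        ]
        Fv = np.stack([np.fft.fftn(v)[low_sel] for v in vols])
        Wv = np.stack(
            [
                (np.abs(np.fft.ifftshift(rotate_data(wedge, R.T)))[low_sel] > 0.5)
                for R in Rs
            ]
        ).astype(float)
        Fm = Fv * Wv
        fnorm = np.sqrt(np.maximum((np.abs(Fm) ** 2).sum(axis=1), 1e-30))
        if references is not None:
            if len(references) != k:
                raise ValueError("need exactly k references")
            means = np.stack([np.fft.fftn(r.data)[low_sel] for r in references])
            assign = np.zeros(n, int)
        else:
            means = None
            assign = rng.permutation(np.arange(n) % k)
        scores = np.zeros(n)
        for it in range(n_iter + (1 if references is not None else 0)):
            if not (it == 0 and means is not None):
                means = np.zeros((k, Fm.shape[1]), complex)
                for c in range(k):
                    sel = assign == c
                    if sel.any():
                        cov = Wv[sel].sum(axis=0)
                        means[c] = Fm[sel].sum(axis=0) / np.maximum(cov, 0.5)
            corr = np.zeros((n, k))
            for c in range(k):
                mc = means[c][None, :] * Wv
                mn = np.sqrt(np.maximum((np.abs(mc) ** 2).sum(axis=1), 1e-30))
                corr[:, c] = (Fm * np.conj(mc)).sum(axis=1).real / (fnorm * mn)
            new_assign = corr.argmax(axis=1)
            scores = corr.max(axis=1)
            if np.array_equal(new_assign, assign) and it > 0:
                break
            assign = new_assign
    else:
        mask = soft_sphere_mask(shape, mask_radius_fraction * min(shape)) > 0.5
        X = np.stack([v[mask] for v in vols])
        X = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(X, axis=1)
        norms[norms == 0] = 1.0
        Xn = X / norms[:, None]
        if references is not None:
            if len(references) != k:
                raise ValueError("need exactly k references")
            means = np.stack([r.data[mask] for r in references])
            means = means - means.mean(axis=1, keepdims=True)
            corr = Xn @ (means / np.linalg.norm(means, axis=1, keepdims=True)).T
            assign = corr.argmax(axis=1)
        else:
            assign = rng.permutation(np.arange(n) % k)
        scores = np.zeros(n)
        for _ in range(n_iter):
            means = np.zeros((k, X.shape[1]))
            for c in range(k):
                sel = assign == c
                if sel.any():
                    means[c] = X[sel].mean(axis=0)
            mn = np.linalg.norm(means, axis=1)
            mn[mn == 0] = 1.0
            corr = Xn @ (means / mn[:, None]).T
            new_assign = corr.argmax(axis=1)
            scores = corr.max(axis=1)
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
    averages = []
    pops = np.zeros(k, int)
    for c in range(k):
        sel = assign == c
        pops[c] = sel.sum()
        acc = np.zeros(shape)
        if sel.any():
            for i in np.flatnonzero(sel):
                acc += vols_raw[i]
            acc /= sel.sum()
        averages.append(Volume(acc, vox))
    return ClassifyResult(assign, averages, pops, scores)


def fit_reference(
    map_volume: Volume,
    reference: Volume,
    search: AngularSearch | None = None,
    lowpass_resolution: float | None = None,
    min_correlation: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rigid-body superposition of a reference into a map.

    Exhaustive coarse rotations plus local refinement and FFT shift search,
    both maps matched with the same low-pass filter first.  Returns
    ``(R, shift_xyz_A, correlation)`` with ``R`` rotating the reference into
    the map.  Raises :class:`NoFitError` if no pose reaches
    ``min_correlation`` (e.g. fitting into pure noise).
    """
    table = align_subtomograms(
        [map_volume], reference, search=search, lowpass_resolution=lowpass_resolution
    )
    row = table.df.iloc[0]
    if row["score"] < min_correlation:
        raise NoFitError(
            f"best correlation {row['score']:.3f} below floor {min_correlation}"
        )
    R = euler_zyz_to_matrix(row["euler_rot"], row["euler_tilt"], row["euler_psi"])
    shift = np.array([row["center_x"], row["center_y"], row["center_z"]])
    return R, shift, float(row["score"])


def apply_transform(reference: Volume, R: np.ndarray, shift_xyz_A: np.ndarray) -> Volume:
    """Pose a reference with a fit_reference transform (for differencing)."""
    vox = reference.voxel_size
    return reference.with_data(
        rotate_data(reference.data, R, shift_xyz=np.asarray(shift_xyz_A) / vox)
    )


def difference_density(
    map_volume: Volume,
    fitted_reference: Volume,
    sigma_threshold: float = 3.0,
    min_blob_volume: float | None = None,
    mask_level: float = 0.1,
) -> BlobReport:
    """Detect densities present in a map but absent from a fitted reference.

    Both maps are z-scored inside a common support mask (reference above
    ``mask_level`` of its maximum, dilated); the positive difference is
    thresholded at ``sigma_threshold`` standard deviations and 26-connected
    components of at least ``min_blob_volume`` (default 5 voxel volumes) are
    reported with centroid (Angstrom), volume and peak height.  An empty
    report is a perfectly valid outcome — identical maps produce one.
    """
    if map_volume.shape != fitted_reference.shape:
        raise ValueError("map and reference must share a grid")
    vox = map_volume.voxel_size
    if min_blob_volume is None:
        min_blob_volume = 5.0 * vox**3
    support = fitted_reference.data > mask_level * fitted_reference.data.max()
    support = ndimage.binary_dilation(support, iterations=3)
    if not support.any():
        raise ValueError("empty reference support")

    def _z(d):
        m = d[support]
        sd = m.std()
        return (d - m.mean()) / (sd if sd > 0 else 1.0)

    a = _z(map_volume.data)
    b = _z(fitted_reference.data)
    diff = (a - b) * support
    hot = diff > sigma_threshold
    labels, n = ndimage.label(hot, structure=np.ones((3, 3, 3)))
    blobs = []
    corr = 0.0
    am, bm = a[support], b[support]
    if am.std() > 0 and bm.std() > 0:
        corr = float(np.corrcoef(am, bm)[0, 1])
    for lab in range(1, n + 1):
        sel = labels == lab
        nvox = int(sel.sum())
        volume = nvox * vox**3
        if volume < min_blob_volume:
            continue
        com = ndimage.center_of_mass(diff * sel)
        centroid = np.array([com[2], com[1], com[0]]) * vox + map_volume.origin
        blobs.append(
            Blob(
                centroid_xyz=centroid,
                volume=volume,
                peak_density=float(diff[sel].max()),
                n_voxels=nvox,
            )
        )
    blobs.sort(key=lambda b: -b.volume)
    return BlobReport(blobs, sigma_threshold, min_blob_volume, corr)
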