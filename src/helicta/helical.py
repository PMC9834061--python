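"""2D-projected helical reconstruction and helical-parameter refinement.

The strategy mirrors the in-situ filament workflow it re-implements: oriented,
centered segments are rotated into the plane and collapsed into 2D projection
images of their central slab; the images are aligned by projection matching
against azimuthal projections of a 3D reference (low-pass filtered to 60 A
when seeding from an external model); aligned images are combined by weighted
back-projection into a 3D map; the helical rise and twist are refined by
maximizing the map's self-correlation under helical symmetry; the map is then
symmetrized and becomes the next iteration's reference.

Image convention: projection images are indexed ``[i, j]`` with ``i`` the
in-plane coordinate perpendicular to the filament and ``j`` the axial
coordinate, i.e. the filament runs horizontally.  ``rot`` is the azimuth of
the segment about the helical axis (the projection-matching angle), ``psi``
the in-plane rotation of the image, shifts are in Angstrom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import iradon

from ._geom import lowpass, masked_correlation, rot_z, rotate_data, volume_center
from .simulate import HelicalParams
from .volume import Volume


@dataclass
class ProjectionStack:
    """A stack of same-sized 2D projection images with per-image alignment."""

    images: np.ndarray          # (N, box, box)
    pixel_size: float           # A / pixel
    table: pd.DataFrame         # particle_id, filament_id, rot, psi, shifts, score

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (N, H, W) array")
        if len(self.table) != len(self.images):
            raise ValueError("table and image stack lengths differ")
        if "score" in self.table.columns and len(self.table):
            if not np.all(np.isfinite(self.table["score"].to_numpy(float))):
                raise ValueError("scores must be finite")

    def __len__(self) -> int:
        return len(self.images)

    def select(self, mask: np.ndarray) -> "ProjectionStack":
        return ProjectionStack(
            self.images[mask], self.pixel_size, self.table[mask].reset_index(drop=True)
        )


@dataclass
class AlignSearch:
    """Projection-matching search settings (angles deg, shifts A)."""

    rot_step: float = 4.0
    psi_range: float = 15.0
    psi_step: float = 3.0
    max_shift: float = 30.0
    max_shift_axial: float | None = None   # default rise/2 downstream
    allow_flip: bool = True                # also try psi ~ 180 (reversed polarity)


@dataclass
class ClassResult:
    averages: np.ndarray        # (k, H, W)
    assignments: np.ndarray     # (N,)
    populations: np.ndarray     # (k,)
    contrast: np.ndarray        # (k,) variance of the average in the filament band


@dataclass
class ReconstructionResult:
    map: Volume
    refined: HelicalParams
    fsc: np.ndarray             # (n_shells, 2): spatial frequency 1/A, correlation
    resolution: float           # A at the configured threshold
    n_particles_used: int
    objective_surface: dict | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.fsc) and (np.any(self.fsc[:, 1] > 1 + 1e-6) or np.any(self.fsc[:, 1] < -1 - 1e-6)):
            raise ValueError("FSC values must lie in [-1, 1]")
        if self.resolution < 2 * self.map.voxel_size - 1e-9:
            raise ValueError("resolution cannot beat Nyquist (2 x voxel size)")


class UnresolvedHelixError(RuntimeError):
    """The helical-parameter objective surface is flat (featureless map)."""


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def project_volume_y(data: np.ndarray, slab_fraction: float = 1.0) -> np.ndarray:
    """Project a [z,y,x] volume along y over a central slab; image is (x, z)."""
    ny = data.shape[1]
    half = max(1, int(round(0.5 * slab_fraction * ny)))
    c = ny // 2
    y0, y1 = max(0, c - half), min(ny, c + half)
    return data[:, y0:y1, :].sum(axis=1).T


def project_segments(
    subvolumes: list[Volume],
    table: pd.DataFrame,
    slab_fraction: float = 1.0 / 3.0,
) -> ProjectionStack:
    """Collapse axis-aligned, centered segments into 2D projection images.

    Each subvolume (filament along z) is viewed side-on and the central slab
    (``slab_fraction`` of the box, default one third) is summed through,
    which suppresses overlap from the far side of the helix.  Equivalent to
    rotating the segment 90 deg into the plane and projecting the central
    slices along the new z.
    """
    if not 0 < slab_fraction <= 1:
        raise ValueError("slab_fraction must lie in (0, 1]")
    if not subvolumes:
        return ProjectionStack(
            np.zeros((0, 2, 2)), 1.0, pd.DataFrame(columns=["particle_id"])
        )
    imgs = np.stack([project_volume_y(s.data, slab_fraction) for s in subvolumes])
    t = table.reset_index(drop=True).copy()
    for col, default in (
        ("rot", 0.0), ("psi", 0.0), ("shift_perp", 0.0), ("shift_axial", 0.0),
        ("score", 0.0), ("class_id", -1), ("flipped", False),
    ):
        if col not in t.columns:
            t[col] = default
    return ProjectionStack(imgs, subvolumes[0].voxel_size, t)


def reference_projections(
    reference: Volume, phis: np.ndarray, slab_fraction: float = 1.0
) -> np.ndarray:
    """Azimuthal projection gallery of a 3D reference (filament along z)."""
    out = np.empty((len(phis), reference.shape[2], reference.shape[0]))
    for i, phi in enumerate(phis):
        rotated = rotate_data(reference.data, rot_z(phi), order=1)
        out[i] = project_volume_y(rotated, slab_fraction)
    return out


# ---------------------------------------------------------------------------
# 2D alignment (projection matching)
# ---------------------------------------------------------------------------


def _norm_image(img: np.ndarray) -> np.ndarray:
    sd = img.std()
    return (img - img.mean()) / sd if sd > 0 else img - img.mean()


def segment_wedge_masks(
    table: pd.DataFrame,
    geometry,
    shape: tuple[int, int],
    pixel_size: float,
) -> np.ndarray:
    """Per-segment 2D missing-wedge footprints of the projection images.

    The 2D Fourier transform of a segment's projection is the central section
    of the (rotated) subvolume transform, so each image inherits the tomogram
    wedge through the segment's orienting rotation (from the stored tangent).
    Returned as (N, H, W) boolean masks in unshifted fft2 layout, used for
    wedge-masked alignment scores.
    """
    from ._geom import minimal_rotation_to_z
    from .simulate import sampled_directions

    H, W = shape
    ki = np.fft.fftfreq(H, d=pixel_size)
    kj = np.fft.fftfreq(W, d=pixel_size)
    KI, KJ = np.meshgrid(ki, kj, indexing="ij")
    # image axes: i = in-plane x' of the oriented segment, j = axial z'
    k_img = np.stack([KI.ravel(), np.zeros(KI.size), KJ.ravel()], axis=1)
    masks = np.empty((len(table), H, W), bool)
    for n in range(len(table)):
        t = table.iloc[n][["tangent_x", "tangent_y", "tangent_z"]].to_numpy(float)
        R1 = minimal_rotation_to_z(t / np.linalg.norm(t))
        k_tomo = k_img @ R1  # rows: R1^T k_img
        masks[n] = sampled_directions(k_tomo, geometry).reshape(H, W)
        masks[n, 0, 0] = False  # drop DC so masked scores are mean-free
    return masks


def _band_mask(shape, pixel_size, resolution, soft_width=0.01):
    """Soft low-pass mask in full fft2 layout (DC removed)."""
    H, W = shape
    ki = np.fft.fftfreq(H, d=pixel_size)
    kj = np.fft.fftfreq(W, d=pixel_size)
    k = np.sqrt(ki[:, None] ** 2 + kj[None, :] ** 2)
    if resolution is None:
        m = np.ones(shape)
    else:
        kc = 1.0 / resolution
        m = np.clip(0.5 * (1.0 + np.cos(np.pi * (k - kc + soft_width) / (2 * soft_width))), 0.0, 1.0)
        m[k <= kc - soft_width] = 1.0
        m[k >= kc + soft_width] = 0.0
    m[0, 0] = 0.0
    return m


def _alignment_scores(
    stack: ProjectionStack,
    reference: Volume,
    search: AlignSearch,
    lowpass_resolution: float | None,
    rise_prior: float | None,
    wedge_masks: np.ndarray | None,
    lattice_resolution: float | None = None,
):
    """Projection-matching score tensors, in one or two frequency bands.

    Returns ``(phis, S, Sl, P, mj)``.  ``S[c, n, r, z]`` is the normalized
    cross-correlation of image n against the reference projection at azimuth
    ``phis[r]``, low-pass filtered to ``lowpass_resolution``, for polarity
    class c (0 upright, 1 in-plane flipped) at axial shift bin z (voxel
    spacing, centered), maximized over the in-plane angle and the
    perpendicular shift window; ``P[c, n, r, z]`` holds the maximizing
    ``(psi, shift_perp)``.  ``Sl`` is the same quantity scored in the wider
    ``lattice_resolution`` band (None when not requested): the envelope band
    determines azimuths, but only a band that includes the subunit-rise
    spacing can register axial phase.
    """
    px = stack.pixel_size
    phis = np.arange(0.0, 360.0, search.rot_step)
    gallery = reference_projections(reference, phis)
    H, W = stack.images.shape[1:]
    B_env = _band_mask((H, W), px, lowpass_resolution)
    two_band = lattice_resolution is not None
    if two_band:
        B_lat = _band_mask((H, W), px, lattice_resolution)
    if wedge_masks is not None:
        pass  # per-image masks multiply the band masks below
    refs_F = np.stack([np.fft.fft2(_norm_image(g)) for g in gallery])
    refs_P = np.abs(refs_F) ** 2
    max_axial = search.max_shift_axial
    if max_axial is None:
        max_axial = 0.5 * (rise_prior if rise_prior else 27.9)
    mi = max(1, int(round(search.max_shift / px)))
    mj = max(1, int(round(max_axial / px)))
    ci, cj = H // 2, W // 2
    psi_offsets = np.arange(-search.psi_range, search.psi_range + 1e-9, search.psi_step)
    npix = H * W
    N = len(stack)
    R = len(phis)
    n_classes = 2 if search.allow_flip else 1
    nzb = 2 * mj + 1  # axial shift bins, voxel-spaced, centered on zero
    S = np.full((n_classes, N, R, nzb), -np.inf)
    Sl = np.full((n_classes, N, R, nzb), -np.inf) if two_band else None
    P = np.zeros((n_classes, N, R, nzb, 2))  # best (psi, shift_perp) per bin

    def _collect(cc, target, params, cls, n, ri, psi_w):
        win = cc[ci - mi:ci + mi + 1, cj - mj:cj + mj + 1]
        ibest = win.argmax(axis=0)  # best perpendicular shift per axial bin
        svals = win[ibest, np.arange(nzb)]
        upd = svals > target[cls, n, ri]
        if upd.any():
            target[cls, n, ri, upd] = svals[upd]
            if params is not None:
                params[cls, n, ri, upd, 0] = psi_w
                params[cls, n, ri, upd, 1] = (ibest[upd] - mi) * px

    for n in range(N):
        img0 = stack.images[n]
        prior = float(stack.table["psi"].iloc[n]) if "psi" in stack.table else 0.0
        prior = 0.0 if not np.isfinite(prior) else prior
        # fold the prior into [-90, 90) so that cls = 1 always means a
        # physical in-plane flip, independent of how the previous round's
        # psi was stored; otherwise the polarity classes would silently
        # swap meaning between iterations
        prior = ((prior + 90.0) % 180.0) - 90.0
        M = wedge_masks[n] if wedge_masks is not None else 1.0
        Be = B_env * M
        env_ref_norms = np.sqrt(np.maximum((refs_P * Be**2).sum(axis=(1, 2)) / npix, 1e-30))
        if two_band:
            Bl = B_lat * M
            lat_ref_norms = np.sqrt(np.maximum((refs_P * Bl**2).sum(axis=(1, 2)) / npix, 1e-30))
        for cls in range(n_classes):
            for off in psi_offsets:
                psi_w = (prior + 180.0 * cls + off) % 360.0
                unrot = (
                    img0
                    if abs(psi_w) < 1e-9
                    else ndimage.rotate(img0, -psi_w, reshape=False, order=1, prefilter=False)
                )
                Fi = np.fft.fft2(_norm_image(unrot))
                env_norm = np.sqrt(max(float((np.abs(Fi * Be) ** 2).sum()) / npix, 1e-30))
                if two_band:
                    lat_norm = np.sqrt(max(float((np.abs(Fi * Bl) ** 2).sum()) / npix, 1e-30))
                for ri in range(R):
                    prod = Fi * np.conj(refs_F[ri])
                    cc = np.fft.fftshift(np.fft.ifft2(prod * Be**2).real) / npix
                    _collect(cc / (env_norm * env_ref_norms[ri]), S, P, cls, n, ri, psi_w)
                    if two_band:
                        ccl = np.fft.fftshift(np.fft.ifft2(prod * Bl**2).real) / npix
                        _collect(
                            ccl / (lat_norm * lat_ref_norms[ri]), Sl, None, cls, n, ri, psi_w
                        )
    return phis, S, Sl, P, mj


def _fill_alignment(stack, phis, S, P, mj, cls_idx, rot_idx, z_idx):
    """Write per-image alignment (class, azimuth, axial bin) into a new stack."""
    px = stack.pixel_size
    t = stack.table.copy()
    N = len(stack)
    rows = [
        (
            float(S[cls_idx[n], n, rot_idx[n], z_idx[n]]),
            float(phis[rot_idx[n]]),
            float(P[cls_idx[n], n, rot_idx[n], z_idx[n], 0]),
            float(P[cls_idx[n], n, rot_idx[n], z_idx[n], 1]),
            float((z_idx[n] - mj) * px),
            bool(cls_idx[n] == 1),
        )
        for n in range(N)
    ]
    t["score"] = [r[0] for r in rows]
    t["rot"] = [r[1] for r in rows]
    t["psi"] = [r[2] for r in rows]
    t["shift_perp"] = [r[3] for r in rows]
    t["shift_axial"] = [r[4] for r in rows]
    t["flipped"] = [r[5] for r in rows]
    return ProjectionStack(stack.images, px, t)


def align_2d(
    stack: ProjectionStack,
    reference: Volume,
    search: AlignSearch | None = None,
    lowpass_resolution: float | None = 60.0,
    rise_prior: float | None = None,
    wedge_masks: np.ndarray | None = None,
) -> ProjectionStack:
    """Assign (rot, psi, shift) to every image by projection matching.

    References are azimuthal projections of ``reference`` (low-pass filtered
    first); for each image the in-plane angle is searched within
    ``psi_range`` of its prior — and, when ``allow_flip``, also around
    psi+180, which is how reversed-polarity segments are recognized — while
    shifts are found by FFT cross-correlation, the axial component limited to
    half a rise so segments cannot slide along the helix by whole subunits.
    Scores are normalized cross-correlations; when per-image ``wedge_masks``
    (from :func:`segment_wedge_masks`) are given, scores are computed over
    the sampled Fourier region only, which removes the orientation-dependent
    bias the missing wedge otherwise imprints on the scores.  Deterministic:
    ties resolve to the first grid point.
    """
    if search is None:
        search = AlignSearch()
    if len(stack) == 0:
        return stack
    phis, S, _, P, mj = _alignment_scores(
        stack, reference, search, lowpass_resolution, rise_prior, wedge_masks
    )
    C, N, R, Z = S.shape
    flat = S.reshape(C, N, R * Z)
    best_rz = flat.argmax(axis=2)
    best_per_class = np.take_along_axis(flat, best_rz[:, :, None], axis=2)[:, :, 0]
    cls_idx = best_per_class.argmax(axis=0)
    rz = best_rz[cls_idx, np.arange(N)]
    rot_idx, z_idx = np.divmod(rz, Z)
    return _fill_alignment(stack, phis, S, P, mj, cls_idx, rot_idx, z_idx)


def align_2d_coherent(
    stack: ProjectionStack,
    reference: Volume,
    prior: "HelicalParams",
    search: AlignSearch | None = None,
    lowpass_resolution: float | None = 60.0,
    wedge_masks: np.ndarray | None = None,
    lattice_phase_step: float | None = None,
    lattice_resolution: float = 18.0,
) -> ProjectionStack:
    """Projection matching with filament-coherent helical-lattice priors.

    A side view of a low-resolution helix is nearly degenerate along a ridge
    of (azimuth, axial shift) combinations — and once the reference is
    low-pass filtered beyond the rise spacing, a single segment carries *no*
    information about its axial phase at all.  Segments of one filament are
    not independent, though: if segment j sits at arc position s_j and the
    filament's subunit lattice has (unknown) phase psi, then the nearest
    lattice point is k_j = round((s_j - psi) / rise) and helical symmetry
    dictates the whole pose,

        azimuth_j = delta + k_j * twist,   axial shift_j = -(s_j - psi - k_j * rise),

    with only three filament-wide unknowns: the lattice phase psi, the
    azimuth offset delta, and the polarity.  This routine scores every
    (psi, delta, polarity) hypothesis against projection-matching score
    tensors in two frequency bands — the heavily filtered envelope band
    (``lowpass_resolution``) pins the azimuth offset, while the wider
    ``lattice_resolution`` band, which still contains the subunit-rise
    spacing, pins the lattice phase — and assigns each segment the pose its
    filament's best hypothesis dictates.  This is the counterpart of helical
    priors in conventional helical-reconstruction packages, and the reason
    the reconstruction retains a subunit lattice even when individual
    filtered images do not resolve it.
    """
    if search is None:
        search = AlignSearch()
    if len(stack) == 0:
        return stack
    phis, S, Sl, P, mj = _alignment_scores(
        stack, reference, search, lowpass_resolution, prior.rise, wedge_masks,
        lattice_resolution=lattice_resolution,
    )
    C, N, R, Z = S.shape
    rot_step = 360.0 / R
    px = stack.pixel_size
    rise, twist = prior.rise, prior.twist
    if lattice_phase_step is None:
        lattice_phase_step = 0.5 * px
    psis_lattice = np.arange(0.0, rise, lattice_phase_step)
    t = stack.table.copy()
    for col in ("score", "rot", "psi", "shift_perp", "shift_axial"):
        if col not in t.columns:
            t[col] = 0.0
    if "flipped" not in t.columns:
        t["flipped"] = False
    for _, g in t.groupby("filament_id"):
        idx = g.index.to_numpy()
        arcs = g["arc_position"].to_numpy(float)
        env_max = S[:, idx].max(axis=3)  # (C, n_seg, R): envelope, z-marginal
        best = (-np.inf, 0, 0.0, None, None, 0)
        for cls in range(C):
            sign = 1.0 if cls == 0 else -1.0
            for psi_l in psis_lattice:
                k = np.round((arcs - psi_l) / rise)
                rho = arcs - psi_l - k * rise  # in [-rise/2, rise/2)
                zb = np.clip(np.round(-sign * rho / px).astype(int) + mj, 0, Z - 1)
                base = np.round(sign * k * twist / rot_step).astype(int) % R
                # envelope band chooses the azimuth offset delta ...
                totals_env = np.zeros(R)
                for j in range(len(idx)):
                    totals_env += np.roll(env_max[cls, j], -base[j])
                d = int(np.argmax(totals_env))
                # ... and the lattice band scores this (psi, delta) hypothesis
                ridx = (d + base) % R
                lat = float(Sl[cls, idx, ridx, zb].sum())
                score = totals_env[d] + lat
                if score > best[0]:
                    best = (score, cls, psi_l, k, ridx, d)
        _, cls, psi_l, k, ridx, d0 = best
        sign = 1.0 if cls == 0 else -1.0
        rho = arcs - psi_l - k * rise
        zb = np.clip(np.round(-sign * rho / px).astype(int) + mj, 0, Z - 1)
        # the hypothesis dictates the exact continuous pose; snapping rot and
        # the axial shift to the search grids would imprint a correlated
        # staircase artifact on the reconstruction
        t.loc[idx, "rot"] = (phis[d0] + sign * k * twist) % 360.0
        t.loc[idx, "shift_axial"] = -sign * rho
        t.loc[idx, "psi"] = P[cls, idx, ridx, zb, 0]
        t.loc[idx, "shift_perp"] = P[cls, idx, ridx, zb, 1]
        t.loc[idx, "score"] = S[cls, idx, ridx, zb]
        t.loc[idx, "flipped"] = cls == 1
    return ProjectionStack(stack.images, px, t)


def _apply_alignment(img: np.ndarray, psi: float, si: float, sj: float, px: float) -> np.ndarray:
    """Bring one image into the reference frame (undo psi, then shifts)."""
    out = img
    if abs(psi % 360.0) > 1e-9:
        out = ndimage.rotate(out, -(psi % 360.0), reshape=False, order=1, prefilter=False)
    if abs(si) > 1e-12 or abs(sj) > 1e-12:
        out = ndimage.shift(out, (-si / px, -sj / px), order=1, prefilter=False)
    return out


def aligned_images(stack: ProjectionStack) -> np.ndarray:
    t = stack.table
    return np.stack(
        [
            _apply_alignment(
                stack.images[n],
                float(t["psi"].iloc[n]),
                float(t["shift_perp"].iloc[n]),
                float(t["shift_axial"].iloc[n]),
                stack.pixel_size,
            )
            for n in range(len(stack))
        ]
    )


# ---------------------------------------------------------------------------
# 2D classification ("without sampling": alignments frozen)
# ---------------------------------------------------------------------------


def classify_2d(
    stack: ProjectionStack, k: int, n_iter: int = 10, seed: int = 0
) -> ClassResult:
    """Reference-free 2D classification with frozen alignments.

    Alternates correlation-based assignment and class averaging, starting
    from a seeded random balanced split.  The per-class contrast score (the
    variance of the class average inside the central filament band) is what
    automated class selection thresholds — the stand-in for picking 'classes
    with visible features' by eye.
    """
    n = len(stack)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of images ({n})")
    imgs = aligned_images(stack)
    flat = imgs.reshape(n, -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1)
    norms[norms == 0] = 1.0
    rng = np.random.default_rng(seed)
    assign = rng.permutation(np.arange(n) % k)
    for _ in range(n_iter):
        means = np.zeros((k, flat.shape[1]))
        for c in range(k):
            sel = assign == c
            if sel.any():
                means[c] = flat[sel].mean(axis=0)
        mnorm = np.linalg.norm(means, axis=1)
        mnorm[mnorm == 0] = 1.0
        corr = (flat / norms[:, None]) @ (means / mnorm[:, None]).T
        new_assign = np.argmax(corr, axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    H, W = imgs.shape[1:]
    averages = np.zeros((k, H, W))
    pops = np.zeros(k, int)
    for c in range(k):
        sel = assign == c
        pops[c] = sel.sum()
        if sel.any():
            averages[c] = imgs[sel].mean(axis=0)
    band = np.zeros((H, W), bool)
    qh = max(2, H // 4)
    band[H // 2 - qh:H // 2 + qh, :] = True
    contrast = np.array([float(a[band].var()) for a in averages])
    return ClassResult(averages, assign, pops, contrast)


def select_classes(result: ClassResult, keep_fraction: float = 0.7) -> np.ndarray:
    """Image mask keeping members of the highest-contrast classes.

    Classes are ranked by contrast and kept until ``keep_fraction`` of the
    images are retained (at least one class always survives).
    """
    order = np.argsort(result.contrast)[::-1]
    total = result.populations.sum()
    kept_classes = []
    acc = 0
    for c in order:
        kept_classes.append(c)
        acc += result.populations[c]
        if acc >= keep_fraction * total:
            break
    return np.isin(result.assignments, kept_classes)


# ---------------------------------------------------------------------------
# 3D reconstruction (weighted back-projection)
# ---------------------------------------------------------------------------


def reconstruct_3d(
    stack: ProjectionStack,
    box: int | None = None,
    weighting: str | None = "ramp",
    min_images: int = 50,
) -> Volume:
    """Weighted back-projection of aligned 2D images into a 3D map.

    All projection directions share the filament axis, so the reconstruction
    separates into independent 2D filtered back-projections per z-slice with
    the images' azimuths as projection angles; the ramp filter supplies the
    sampling-density weighting for this single-axis geometry.  Fewer than
    ``min_images`` images triggers a low-confidence warning (the map is
    still computed; a single image back-projects into an azimuthal smear).
    """
    if len(stack) == 0:
        raise ValueError("cannot reconstruct from an empty stack")
    if len(stack) < min_images:
        warnings.warn(
            f"only {len(stack)} images: reconstruction is low-confidence", stacklevel=2
        )
    imgs = aligned_images(stack)
    N, H, W = imgs.shape
    if box is None:
        box = H
    phis = stack.table["rot"].to_numpy(float)
    # sinogram per z-slice: detector axis = image axis i (perpendicular)
    recon = np.empty((W, box, box))
    theta = phis
    for j in range(W):
        sino = imgs[:, :, j].T  # (detector, n_angles)
        recon[j] = iradon(
            sino,
            theta=theta,
            output_size=box,
            filter_name=weighting,
            circle=True,
            preserve_range=True,
        )
    vol = Volume(recon, stack.pixel_size)
    vol.low_confidence = len(stack) < min_images  # type: ignore[attr-defined]
    return vol


# ---------------------------------------------------------------------------
# helical symmetry
# ---------------------------------------------------------------------------


def _symmetry_order(shape, voxel_size: float, rise: float, z_extent_fraction: float) -> int:
    nz = shape[0]
    reach = 0.5 * (1.0 - z_extent_fraction) * nz * voxel_size
    return int(np.floor(reach / rise + 1e-9))


def symmetrize_helix(
    map_volume: Volume,
    params: HelicalParams,
    z_extent_fraction: float = 0.6,
    order: int = 3,
) -> Volume:
    """Impose helical symmetry by real-space averaging over symmetry mates.

    The map is averaged with its copies shifted by k*rise and rotated by
    k*twist for every k that keeps the central ``z_extent_fraction`` of the
    box inside the volume (k = 0 is always included).  Cubic-spline
    interpolation is used here (unlike the trilinear default elsewhere)
    because the operation may be applied repeatedly and linear interpolation
    would blur the map a little further on every pass.
    """
    if not 0 < z_extent_fraction <= 1:
        raise ValueError("z_extent_fraction must lie in (0, 1]")
    vox = map_volume.voxel_size
    if params.rise < vox:
        raise ValueError(
            f"rise {params.rise} A below voxel size {vox} A: symmetry unresolvable"
        )
    K = _symmetry_order(map_volume.shape, vox, params.rise, z_extent_fraction)
    acc = np.array(map_volume.data, float, copy=True)
    ones = np.ones_like(acc)
    weight = np.ones_like(acc)
    for k in range(-K, K + 1):
        if k == 0:
            continue
        shift = np.array([0.0, 0.0, k * params.rise / vox])
        R = rot_z(k * params.twist)
        acc += rotate_data(map_volume.data, R, shift_xyz=shift, order=order)
        # validity weight: voxels whose symmetry mate fell outside the box
        # must not be diluted toward zero by the averaging
        weight += rotate_data(ones, R, shift_xyz=shift, order=1)
    return map_volume.with_data(acc / np.maximum(weight, 0.5))


def helical_residual(data: np.ndarray, suppress_z_invariant: bool = True) -> np.ndarray:
    """Subtract the azimuthal (ring) average about the z-axis.

    A filament map is dominated by its smooth, nearly cylindrical mean
    density, which correlates highly with *any* symmetrized copy of itself;
    removing the per-(z, r) ring average leaves exactly the rise/twist-
    dependent modulation that helical-parameter refinement must lock onto.
    The per-column z-average is removed as well: z-invariant residuals (most
    prominently the angular-sampling streaks of back-projection from few
    azimuths) are self-similar under a twist of 0 mod 180 deg at any rise
    and would otherwise bias the refinement toward that alias.
    """
    nz, ny, nx = data.shape
    cy, cx = ny // 2, nx // 2
    yy, xx = np.meshgrid(np.arange(ny) - cy, np.arange(nx) - cx, indexing="ij")
    r = np.sqrt(yy**2 + xx**2)
    # half-voxel radial bins keep the binning residue of smooth circular
    # features (soft cylinder edges) well below any genuine helical signal
    nbins = int(np.ceil(2 * r.max())) + 1
    ri = np.clip(np.round(2 * r).astype(int), 0, nbins - 1).ravel()
    counts = np.bincount(ri, minlength=nbins).astype(float)
    counts[counts == 0] = 1.0
    out = np.empty_like(data, dtype=float)
    for z in range(nz):
        sums = np.bincount(ri, weights=data[z].ravel(), minlength=nbins)
        ringmean = (sums / counts)[ri].reshape(ny, nx)
        out[z] = data[z] - ringmean
    if suppress_z_invariant:
        out -= out.mean(axis=0, keepdims=True)
    return out


def refine_helical_params(
    map_volume: Volume,
    prior: HelicalParams,
    rise_range: float | None = None,
    rise_step: float = 0.5,
    twist_range: float = 10.0,
    twist_step: float = 0.5,
    fine_step: float = 0.1,
    z_extent_fraction: float = 0.6,
    mask_radius: float = 60.0,
    flat_epsilon: float = 1e-3,
    min_residual_fraction: float = 0.02,
) -> tuple[HelicalParams, dict]:
    """Grid-search rise and twist by maximizing helical self-correlation.

    The objective at (rise, twist) is the correlation, over a central
    cylindrical mask, between the map and the average of its symmetry mates
    under those parameters, both taken after subtraction of the azimuthal
    ring average (see :func:`helical_residual`) so the smooth cylindrical
    density does not swamp the helical signal.  A full coarse grid (default 0.5 A / 0.5 deg over
    rise +-15% and twist +-10 deg around the prior) is evaluated and returned
    for diagnostics; the peak is then re-gridded at ``fine_step`` and finished
    with parabolic sub-step interpolation.

    Raises :class:`UnresolvedHelixError` when the map carries no helical
    signal: either the azimuthal residual is a negligible fraction of the
    density (a featureless cylinder) or the coarse surface is flat (spread
    below ``flat_epsilon``).  ``mask_radius`` (A) bounds the cylindrical
    evaluation region; the default generously covers an actin-like filament.
    """
    vox = map_volume.voxel_size
    raw = np.asarray(map_volume.data, float)
    # coarse stage: streak-suppressed residual (robust to the twist ~ 180
    # alias of z-invariant back-projection artifacts); fine stage: full
    # ring-subtracted residual (unbiased — the z-mean removal also clips the
    # slow crossover component and would bias the final estimate)
    data = helical_residual(raw, suppress_z_invariant=True)
    data_full = helical_residual(raw, suppress_z_invariant=False)
    nz, ny, nx = data.shape
    if rise_range is None:
        rise_range = 0.15 * prior.rise
    # central cylindrical evaluation mask
    c = volume_center(data.shape)  # xyz
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    r = np.sqrt((xx - c[0]) ** 2 + (yy - c[1]) ** 2)
    zc = np.abs(zz - c[2])
    mask = (r <= min(mask_radius / vox, 0.45 * min(nx, ny))) & (
        zc <= 0.5 * z_extent_fraction * nz
    )
    res_frac = np.linalg.norm(data[mask]) / max(
        np.linalg.norm((raw - raw[mask].mean())[mask]), 1e-30
    )
    if res_frac < min_residual_fraction:
        raise UnresolvedHelixError(
            f"azimuthal residual is only {res_frac:.1%} of the masked density: "
            "the map is featureless about its axis (e.g. a smooth cylinder)"
        )
    pts = np.stack([xx[mask], yy[mask], zz[mask]], axis=1).astype(float)  # xyz vox
    K = _symmetry_order(data.shape, vox, max(prior.rise - rise_range, vox), z_extent_fraction)
    K = max(K, 1)
    rel = pts - c  # xyz offsets from center, voxels

    def make_objective(vol3d):
        a = vol3d[mask]
        a = a - a.mean()
        a_norm = np.linalg.norm(a)

        def objective(rise: float, twist: float) -> float:
            # average of the correlations with each *non-trivial* symmetry
            # mate (k != 0).  Correlating with the mean of the mates instead
            # would be biased: mates that disagree with each other shrink
            # the mean's norm, which inflates the normalized correlation at
            # wrong parameters.
            total = 0.0
            cnt = 0
            for k in range(-K, K + 1):
                if k == 0:
                    continue
                t = np.array([0.0, 0.0, k * rise / vox])
                Rinv = rot_z(-k * twist)
                src = (Rinv @ (rel - t).T).T + c
                b = ndimage.map_coordinates(
                    vol3d, src[:, ::-1].T, order=1, mode="constant", cval=0.0,
                    prefilter=False,
                )
                b = b - b.mean()
                bn = np.linalg.norm(b)
                if a_norm > 0 and bn > 0:
                    total += float(np.dot(a, b) / (a_norm * bn))
                cnt += 1
            return total / cnt if cnt else 0.0

        return objective

    objective = make_objective(data)
    objective_full = make_objective(data_full)

    rises = np.arange(prior.rise - rise_range, prior.rise + rise_range + 1e-9, rise_step)
    twists = np.arange(prior.twist - twist_range, prior.twist + twist_range + 1e-9, twist_step)
    surface = np.empty((len(rises), len(twists)))
    for i, ri in enumerate(rises):
        for j, tw in enumerate(twists):
            surface[i, j] = objective(ri, tw)
    spread = float(np.ptp(surface))
    if spread < flat_epsilon:
        raise UnresolvedHelixError(
            f"objective surface is flat (spread {spread:.2e} < {flat_epsilon}): "
            "the map carries no helical signal"
        )
    i0, j0 = np.unravel_index(np.argmax(surface), surface.shape)
    best_rise, best_twist = rises[i0], twists[j0]

    # fine local grid, scored on the full residual (stage two)
    fr = np.arange(best_rise - 1.5 * rise_step - 1e-12, best_rise + 1.5 * rise_step + 1e-9, fine_step)
    ft = np.arange(best_twist - 2.0 * twist_step - 1e-12, best_twist + 2.0 * twist_step + 1e-9, fine_step)
    fine = np.empty((len(fr), len(ft)))
    for i, ri in enumerate(fr):
        for j, tw in enumerate(ft):
            fine[i, j] = objective_full(ri, tw)
    fi, fj = np.unravel_index(np.argmax(fine), fine.shape)

    def _parab(v, i, step):
        if 0 < i < len(v) - 1:
            d = v[i - 1] - 2 * v[i] + v[i + 1]
            if d < 0:
                return 0.5 * (v[i - 1] - v[i + 1]) / d * step
        return 0.0

    rise_hat = float(fr[fi] + _parab(fine[:, fj], fi, fine_step))
    twist_hat = float(ft[fj] + _parab(fine[fi, :], fj, fine_step))
    twist_hat = (twist_hat + 180.0) % 360.0 - 180.0  # wrap into (-180, 180]
    if twist_hat == -180.0:
        twist_hat = 180.0
    diag = {
        "rise_grid": rises,
        "twist_grid": twists,
        "objective": surface,
        "fine_rise_grid": fr,
        "fine_twist_grid": ft,
        "fine_objective": fine,
    }
    return HelicalParams(rise_hat, twist_hat), diag


# ---------------------------------------------------------------------------
# polarity voting
# ---------------------------------------------------------------------------


def assign_polarity_3d(
    subvolumes: list[Volume],
    table: pd.DataFrame,
    reference: Volume,
    azimuth_step: float = 10.0,
    rise_prior: float = 27.9,
    mask_radius: float = 60.0,
    z_fraction: float = 0.7,
) -> pd.DataFrame:
    """Score each oriented segment subvolume against both polarities in 3D.

    The 2D in-plane alignment is weakly sensitive to filament polarity (a
    projection discards most of the asymmetry), so — mirroring the workflow
    step that maps 2D orientations back into the subvolumes — each segment is
    correlated in 3D against rotated/axially-shifted copies of the polar
    reference and of its in-plane 180 deg flip.  Sets/overwrites the
    ``flipped`` column (plus ``polarity_margin``, the score difference) in a
    copy of ``table``.
    """
    from ._geom import rot_x

    if not subvolumes:
        return table.copy()
    box = subvolumes[0].shape[0]
    vox = subvolumes[0].voxel_size
    c = box // 2
    zz, yy, xx = np.meshgrid(*(np.arange(box),) * 3, indexing="ij")
    r = np.sqrt((xx - c) ** 2 + (yy - c) ** 2)
    mask = (r <= mask_radius / vox) & (np.abs(zz - c) <= 0.5 * z_fraction * box)
    ref_flip = rotate_data(reference.data, rot_x(180.0))
    max_shift = max(1, int(np.ceil(0.5 * rise_prior / vox)))
    shifts = range(-max_shift, max_shift + 1)
    lib = []
    is_flip = []
    for flip, base in ((False, reference.data), (True, ref_flip)):
        for az in np.arange(0.0, 360.0, azimuth_step):
            for dz in shifts:
                v = rotate_data(base, rot_z(az), shift_xyz=np.array([0.0, 0.0, float(dz)]))
                m = v[mask]
                m = m - m.mean()
                n = np.linalg.norm(m)
                lib.append(m / n if n > 0 else m)
                is_flip.append(flip)
    lib = np.asarray(lib)
    is_flip = np.asarray(is_flip)
    S = np.asarray([s.data[mask] for s in subvolumes])
    S = S - S.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(S, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    cc = (S / norms) @ lib.T
    best_up = cc[:, ~is_flip].max(axis=1)
    best_fl = cc[:, is_flip].max(axis=1)
    out = table.reset_index(drop=True).copy()
    out["flipped"] = best_fl > best_up
    out["polarity_margin"] = np.abs(best_up - best_fl)
    return out


def vote_polarity(table: pd.DataFrame, apply: bool = False):
    """Per-filament majority vote over segment polarity.

    A segment counts as 'down' when its in-plane solution required a ~180 deg
    flip (``flipped`` column from :func:`align_2d`).  Confidence is the
    majority fraction; single-segment filaments are flagged as singletons.
    By default the vote is diagnostic only and alignments are untouched —
    matching the workflow this re-implements, where voting results were not
    applied to the reconstruction; with ``apply=True`` minority segments are
    flipped (psi rotated by 180 deg) for users whose data resolves polarity.

    Returns ``(votes_df, table)``; ``table`` is the (possibly modified) input.
    """
    if "flipped" not in table.columns:
        raise ValueError("table has no 'flipped' alignment column; run align_2d first")
    votes = []
    out = table.copy()
    for fid, g in table.groupby("filament_id"):
        n_down = int(g["flipped"].sum())
        n_up = len(g) - n_down
        polarity = "up" if n_up >= n_down else "down"
        confidence = max(n_up, n_down) / len(g)
        votes.append(
            dict(
                filament_id=fid,
                polarity=polarity,
                confidence=confidence,
                n_segments=len(g),
                singleton=len(g) == 1,
            )
        )
        if apply:
            minority = g.index[g["flipped"] != (polarity == "down")]
            out.loc[minority, "psi"] = (out.loc[minority, "psi"] + 180.0) % 360.0
            out.loc[minority, "flipped"] = polarity == "down"
    return pd.DataFrame(votes), out


# ---------------------------------------------------------------------------
# Fourier shell correlation
# ---------------------------------------------------------------------------


def compute_fsc(
    half_a: Volume,
    half_b: Volume,
    mask: np.ndarray | None = None,
    threshold: float = 0.143,
) -> tuple[np.ndarray, float]:
    """Fourier shell correlation between two half-maps and the resolution at
    the first threshold crossing (linearly interpolated).

    Half-sets must be split by filament, never by segment — neighbouring
    segments overlap and would inflate the correlation.  Identical maps give
    FSC = 1 in every shell and a resolution at Nyquist (2 x voxel).
    """
    if half_a.shape != half_b.shape:
        raise ValueError(f"grid mismatch: {half_a.shape} vs {half_b.shape}")
    if abs(half_a.voxel_size - half_b.voxel_size) > 1e-6:
        raise ValueError("voxel sizes differ")
    a = half_a.data
    b = half_b.data
    if mask is not None:
        a = a * mask
        b = b * mask
    Fa = np.fft.fftn(a)
    Fb = np.fft.fftn(b)
    n = min(a.shape)
    vox = half_a.voxel_size
    grids = np.meshgrid(*[np.fft.fftfreq(s) * s for s in a.shape], indexing="ij")
    rad = np.sqrt(sum(g * g for g in grids))
    shell = np.round(rad * n / min(a.shape)).astype(int)  # integer shell index
    nsh = n // 2
    num = np.zeros(nsh)
    da = np.zeros(nsh)
    db = np.zeros(nsh)
    flat = shell.ravel()
    sel = flat < nsh
    np.add.at(num, flat[sel], (Fa.ravel()[sel] * np.conj(Fb.ravel()[sel])).real)
    np.add.at(da, flat[sel], np.abs(Fa.ravel()[sel]) ** 2)
    np.add.at(db, flat[sel], np.abs(Fb.ravel()[sel]) ** 2)
    den = np.sqrt(da * db)
    fsc = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    fsc = np.clip(fsc, -1.0, 1.0)
    freq = np.arange(nsh) / (n * vox)
    curve = np.stack([freq, fsc], axis=1)
    resolution = 2.0 * vox  # Nyquist if the curve never crosses
    for s in range(1, nsh):
        if fsc[s] < threshold <= fsc[s - 1]:
            f0, f1 = freq[s - 1], freq[s]
            c0, c1 = fsc[s - 1], fsc[s]
            fc = f0 + (c0 - threshold) / (c0 - c1) * (f1 - f0)
            resolution = float(1.0 / fc)
            break
    return curve, max(resolution, 2.0 * vox)
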