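"""Filament segmentation: traces -> oriented, centered subvolume segments.

Picked centerlines (here: ground-truth traces from the simulator, or traces
imported as tables) are cut into overlapping segments at a fixed arc-length
spacing — 32.13 A by default, matching the intersegment distance used for
the Lokiactin filaments — and each segment is extracted as a cubic subvolume,
rotated so the local filament tangent lies along +z, and centered in x/y by
correlation against a featureless soft-edged cylinder.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from ._geom import (
    minimal_rotation_to_z,
    matrix_to_euler_zyz,
    rotate_data,
    volume_center,
)
from .simulate import _trace_spline
from .tables import FilamentTrace, ParticleTable
from .volume import Volume

logger = logging.getLogger(__name__)


def segment_trace(
    trace: FilamentTrace, spacing: float, start_particle_id: int = 0
) -> ParticleTable:
    """Cut a trace into segments every ``spacing`` Angstrom of arc length.

    Segments sit at arc positions 0, s, 2s, ... <= L, giving
    ``floor(L / s) + 1`` of them; the tangent is the unit derivative of the
    interpolated centerline.  Euler angles are the ZYZ triple of the minimal
    rotation taking +z onto the tangent (in-plane azimuth free by
    convention — it is a search parameter downstream).
    """
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    spl, tt, arc = _trace_spline(trace.control_points)
    L = float(arc[-1])
    if L < spacing:
        warnings.warn(
            f"trace {trace.filament_id} shorter than one spacing "
            f"({L:.1f} < {spacing} A): single segment at arc 0"
        )
        s_vals = np.array([0.0])
    else:
        n = int(np.floor(L / spacing + 1e-9)) + 1
        s_vals = np.arange(n) * spacing
    t_of_s = np.interp(s_vals, arc, tt)
    pos = spl(t_of_s)
    tang = spl.derivative()(t_of_s)
    tang = tang / np.linalg.norm(tang, axis=1, keepdims=True)
    rows = []
    for i, (s, p, t) in enumerate(zip(s_vals, pos, tang)):
        R = minimal_rotation_to_z(t).T  # reference(+z) -> particle(tangent)
        rot, tilt, psi = matrix_to_euler_zyz(R)
        rows.append(
            dict(
                particle_id=start_particle_id + i,
                source_volume_id=trace.source_volume_id,
                filament_id=trace.filament_id,
                center_x=p[0],
                center_y=p[1],
                center_z=p[2],
                euler_rot=rot,
                euler_tilt=tilt,
                euler_psi=psi,
                arc_position=float(s),
                tangent_x=t[0],
                tangent_y=t[1],
                tangent_z=t[2],
            )
        )
    return ParticleTable(pd.DataFrame(rows))


def segment_traces(traces: list[FilamentTrace], spacing: float) -> ParticleTable:
    """Segment several traces into one table with globally unique ids."""
    parts = []
    next_id = 0
    for tr in traces:
        t = segment_trace(tr, spacing, start_particle_id=next_id)
        next_id += len(t)
        parts.append(t.df)
    return ParticleTable(pd.concat(parts, ignore_index=True))


def extract_subvolumes(
    volume: Volume, table: ParticleTable, box: int
) -> tuple[list[Volume], np.ndarray]:
    """Extract one cubic, segment-centered subvolume per table row.

    Sub-voxel centers are handled by trilinear interpolation; segments whose
    box would leave the tomogram are dropped (the count is logged) and
    flagged False in the returned keep-mask.  The subvolume convention places
    the segment center at voxel ``box // 2`` on each axis.
    """
    if box % 2:
        raise ValueError("box size must be even")
    nz, ny, nx = volume.shape
    if box > min(nz, ny, nx):
        raise ValueError(f"box {box} exceeds volume dimensions {volume.shape}")
    centers = table.centers()
    vox = volume.voxel_size
    offs = np.arange(box) - box // 2
    oz, oy, ox = np.meshgrid(offs, offs, offs, indexing="ij")
    subs: list[Volume] = []
    keep = np.ones(len(table), dtype=bool)
    for i, c in enumerate(centers):
        cv = (c - volume.origin) / vox  # xyz voxel coords
        zc, yc, xc = cv[2], cv[1], cv[0]
        if (
            zc - box // 2 < 0 or zc + box // 2 > nz - 1
            or yc - box // 2 < 0 or yc + box // 2 > ny - 1
            or xc - box // 2 < 0 or xc + box // 2 > nx - 1
        ):
            keep[i] = False
            continue
        coords = np.stack([oz + zc, oy + yc, ox + xc]).reshape(3, -1)
        data = ndimage.map_coordinates(
            volume.data, coords, order=1, mode="constant", cval=0.0, prefilter=False
        ).reshape(box, box, box)
        sub_origin = c - (box // 2) * vox
        subs.append(Volume(data, vox, origin=sub_origin))
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("extract_subvolumes: dropped %d/%d border segments", n_drop, len(table))
    return subs, keep


def orient_to_axis(subvolume: Volume, tangent: np.ndarray) -> Volume:
    """Rotate a subvolume so the filament tangent maps onto +z.

    Uses the minimal rotation (in-plane azimuth fixed to 0 by convention);
    for an antiparallel tangent this is a 180 deg flip about an in-plane
    axis, which reverses the axial density profile.
    """
    t = np.asarray(tangent, float)
    n = np.linalg.norm(t)
    if n == 0:
        raise ValueError("tangent must be non-zero")
    R = minimal_rotation_to_z(t / n)
    if np.allclose(R, np.eye(3)):
        return subvolume.copy()
    return subvolume.with_data(rotate_data(subvolume.data, R, order=1))


def cylinder_reference(
    box: int, voxel_size: float, radius: float = 40.0, soft_vox: float = 2.0
) -> Volume:
    """Featureless cylinder along z with a soft (cosine) edge.

    Default radius 40 A — a deliberately smooth, unbiased centering target
    slightly wider than an actin-like filament.
    """
    c = box // 2
    yy, xx = np.meshgrid(np.arange(box) - c, np.arange(box) - c, indexing="ij")
    r = np.sqrt(xx**2 + yy**2) * voxel_size
    rim = radius
    soft = soft_vox * voxel_size
    disc = np.where(
        r <= rim - soft,
        1.0,
        np.where(r >= rim + soft, 0.0, 0.5 * (1 + np.cos(np.pi * (r - rim + soft) / (2 * soft)))),
    )
    data = np.repeat(disc[None, :, :], box, axis=0)
    return Volume(data, voxel_size)


def center_on_cylinder(
    subvolume: Volume,
    cylinder_radius: float = 40.0,
    max_shift: float | None = None,
) -> tuple[np.ndarray, Volume]:
    """Translation-only x/y centering against a featureless cylinder.

    Because the reference is z-invariant, the 3D correlation reduces to a 2D
    correlation of the z-projected subvolume with a soft disc; the peak is
    refined to sub-voxel precision by parabolic interpolation.  The z-shift
    is fixed at 0 (axial position is a helical search parameter, not a
    centering one).  Returns ``(shift_xy_A, shifted_volume)``.
    """
    data = subvolume.data
    if np.ptp(data) == 0:
        warnings.warn("flat subvolume: centering is undefined, zero shift returned")
        return np.zeros(2), subvolume.copy()
    box = data.shape[1]
    vox = subvolume.voxel_size
    if max_shift is None:
        max_shift = 0.25 * box * vox
    proj = data.mean(axis=0)
    ref = cylinder_reference(box, vox, cylinder_radius).data[0]
    proj = proj - proj.mean()
    ref = ref - ref.mean()
    cc = np.fft.irfft2(np.fft.rfft2(proj) * np.conj(np.fft.rfft2(ref)), s=proj.shape)
    cc = np.fft.fftshift(cc)  # index (box//2, box//2) <-> zero shift
    ctr = box // 2
    max_vox = int(max_shift / vox)
    win = cc[ctr - max_vox:ctr + max_vox + 1, ctr - max_vox:ctr + max_vox + 1]
    iy, ix = np.unravel_index(np.argmax(win), win.shape)
    # parabolic sub-voxel refinement (guarded at window edges)
    def _sub(v, i):
        if 0 < i < len(v) - 1:
            d = v[i - 1] - 2 * v[i] + v[i + 1]
            if d != 0:
                return i + 0.5 * (v[i - 1] - v[i + 1]) / d
        return float(i)
    fy = _sub(win[:, ix], iy) - max_vox
    fx = _sub(win[iy, :], ix) - max_vox
    # cc peak at positive (fy, fx) means the density sits at +shift; recenter
    shift_xy = np.array([fx, fy]) * vox
    shifted = ndimage.shift(
        data, (0.0, -fy, -fx), order=1, mode="constant", cval=0.0, prefilter=False
    )
    return shift_xy, subvolume.with_data(shifted)


def prepare_segments(
    tomograms: list[Volume],
    traces: list[FilamentTrace],
    spacing: float,
    box: int,
    cylinder_radius: float = 40.0,
) -> tuple[list[Volume], ParticleTable]:
    """Full segmentation stage: segment, extract, orient, center.

    ``tomograms`` are indexed by ``source_volume_id``.  Returns the oriented,
    centered subvolumes and the matching (border-filtered) segment table with
    the recovered x/y centering shifts recorded in ``shift_x``/``shift_y``.
    """
    table = segment_traces(traces, spacing)
    by_vol: dict[int, Volume] = {}
    for tr in traces:
        by_vol[tr.source_volume_id] = tomograms[tr.source_volume_id]
    subs: list[Volume] = []
    rows = []
    for vid, g in table.df.groupby("source_volume_id"):
        vol = by_vol[int(vid)]
        sub_list, keep = extract_subvolumes(vol, ParticleTable(g), box)
        kept = g[keep].reset_index(drop=True)
        for j, sub in enumerate(sub_list):
            t = kept.iloc[j][["tangent_x", "tangent_y", "tangent_z"]].to_numpy(float)
            oriented = orient_to_axis(sub, t)
            shift_xy, centered = center_on_cylinder(oriented, cylinder_radius)
            row = kept.iloc[j].to_dict()
            row["shift_x"], row["shift_y"] = shift_xy
            rows.append(row)
            subs.append(centered)
    out_table = ParticleTable(pd.DataFrame(rows).sort_values("particle_id").reset_index(drop=True))
    order = np.argsort([r["particle_id"] for r in rows])
    subs = [subs[i] for i in order]
    return subs, out_table
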