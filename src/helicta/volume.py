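"""The :class:`Volume` container and MRC2014 map input/output.

A :class:`Volume` is the universal currency of the package: a 3D scalar grid
with an isotropic physical voxel size in Angstrom and a physical origin (the
coordinate of the center of voxel ``(0, 0, 0)``).  Data arrays are indexed
``[z, y, x]``; all physical coordinates in tables and function signatures are
``(x, y, z)`` in Angstrom.

Maps are stored as standard MRC2014 mode-2 (float32) files via gemmi, so they
open in ChimeraX/IMOD/RELION without conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np


class VolumeFormatError(ValueError):
    """Raised when an on-disk map cannot be interpreted as a valid MRC volume."""


@dataclass
class Volume:
    """3D density grid with physical scale.

    Parameters
    ----------
    data:
        3D array indexed ``[z, y, x]``.
    voxel_size:
        Isotropic voxel edge in Angstrom; must be positive.
    origin:
        Physical xyz coordinate (Angstrom) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if any(n < 1 for n in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a length-3 xyz vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size, self.origin.copy())

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume sharing this one's scale/origin but holding ``data``."""
        return Volume(data, self.voxel_size, self.origin.copy())

    def physical_extent(self) -> np.ndarray:
        """Box edge lengths (x, y, z) in Angstrom."""
        nz, ny, nx = self.data.shape
        return np.array([nx, ny, nz]) * self.voxel_size


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume as an MRC2014 mode-2 map.

    The voxel size is recorded through the header cell dimensions
    (cell edge = n_voxels * voxel_size per axis) and the physical origin in
    the MRC ORIGIN header words.
    """
    if not isinstance(volume, Volume):
        raise TypeError("write_volume expects a Volume")
    path = Path(path)
    # gemmi grids are indexed [u, v, w] = [x, y, z]
    arr = np.ascontiguousarray(volume.data.transpose(2, 1, 0).astype(np.float32))
    grid = gemmi.FloatGrid(arr)
    nz, ny, nx = volume.data.shape
    v = volume.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(nx * v, ny * v, nz * v, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    ox, oy, oz = volume.origin
    m.set_header_float(50, float(ox))
    m.set_header_float(51, float(oy))
    m.set_header_float(52, float(oz))
    m.write_ccp4_map(str(path))


def read_volume(path: str | Path) -> Volume:
    """Read an MRC/CCP4 map into a :class:`Volume`.

    Raises
    ------
    VolumeFormatError
        If the file is truncated or its header is malformed; the message names
        the offending aspect of the file.  No partial Volume is ever returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise VolumeFormatError(f"not a readable MRC map: {path} ({exc})") from exc
    grid = m.grid
    arr = np.array(grid, copy=True)
    if arr.ndim != 3 or min(arr.shape) < 1:
        raise VolumeFormatError(f"map grid in {path} is not a 3D volume (header field N)")
    cell = grid.unit_cell
    nx, ny, nz = arr.shape  # gemmi grid index order is [x, y, z]
    vox = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    if not np.all(vox > 0) or not np.all(np.isfinite(vox)):
        raise VolumeFormatError(f"non-positive cell dimensions in {path} (header field CELLA)")
    if np.ptp(vox) > 1e-3 * vox.mean():
        raise VolumeFormatError(
            f"anisotropic voxel size {vox} in {path}; only isotropic maps are supported"
        )
    origin = np.array(
        [m.header_float(50), m.header_float(51), m.header_float(52)], dtype=float
    )
    data = arr.transpose(2, 1, 0).astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise VolumeFormatError(f"non-finite density values in {path} (data block)")
    return Volume(data, float(vox.mean()), origin)
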