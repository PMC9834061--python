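"""Particle/segment metadata tables and filament traces, with STAR/TSV I/O.

Column dictionary (all coordinates in Angstrom, all angles in degrees,
Euler convention intrinsic ZYZ rotating the reference into the particle):

===================  =========================================================
column               meaning
===================  =========================================================
particle_id          unique integer id of the particle/segment
source_volume_id     id of the tomogram the particle came from
center_x/y/z         particle center, physical Angstrom
euler_rot            first ZYZ Euler angle (azimuth about z)
euler_tilt           second ZYZ Euler angle (out-of-plane tilt)
euler_psi            third ZYZ Euler angle (in-plane)
filament_id          (optional) id of the parent filament
arc_position         (optional) arc length along the filament, Angstrom
tangent_x/y/z        (optional) unit tangent of the filament at the segment
class_id             (optional) classification assignment
score                (optional) alignment/classification score
polarity_flag        (optional) +1 segment points along the trace, -1 flipped
===================  =========================================================

Tables are written as STAR files (one ``data_particles`` block with a loop of
``_helicta_<column>`` tags) and parsed back with gemmi's STAR/CIF reader;
plain tab-separated files are accepted as a fallback dialect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

MANDATORY_COLUMNS = (
    "particle_id",
    "center_x",
    "center_y",
    "center_z",
    "euler_rot",
    "euler_tilt",
    "euler_psi",
)

_TAG_PREFIX = "_helicta_"
_BLOCK_NAME = "particles"


class TableSchemaError(ValueError):
    """A metadata table is missing mandatory columns."""


class ParticleTable:
    """Thin validated wrapper around a pandas DataFrame of particle metadata.

    The underlying frame is exposed as ``.df``; unknown columns are preserved
    through round-trips so foreign metadata survives the pipeline.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise TableSchemaError(f"missing mandatory columns: {missing}")
        if len(df) and df["particle_id"].duplicated().any():
            raise ValueError("particle_id values must be unique")
        ang = df[["euler_rot", "euler_tilt", "euler_psi"]].to_numpy(float)
        if len(df) and not np.all(np.isfinite(ang)):
            raise ValueError("euler angles must be finite")
        if "arc_position" in df.columns and len(df):
            arc = df["arc_position"].to_numpy(float)
            if np.any(arc[np.isfinite(arc)] < 0):
                raise ValueError("arc_position must be non-negative")
            if "filament_id" in df.columns:
                for _, g in df.groupby("filament_id"):
                    a = g["arc_position"].to_numpy(float)
                    if len(a) > 1 and np.any(np.diff(a) <= 0):
                        raise ValueError(
                            "arc_position must be strictly increasing within a filament"
                        )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def centers(self) -> np.ndarray:
        """(N, 3) array of xyz centers in Angstrom."""
        return self.df[["center_x", "center_y", "center_z"]].to_numpy(float)

    def eulers(self) -> np.ndarray:
        """(N, 3) array of (rot, tilt, psi) in degrees."""
        return self.df[["euler_rot", "euler_tilt", "euler_psi"]].to_numpy(float)

    def copy(self) -> "ParticleTable":
        return ParticleTable(self.df.copy())


@dataclass
class FilamentTrace:
    """An ordered polyline of picked control points along one filament."""

    filament_id: int
    control_points: np.ndarray  # (N, 3) xyz Angstrom
    source_volume_id: int = 0

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.ndim != 2 or self.control_points.shape[1] != 3:
            raise ValueError("control_points must be (N, 3) xyz")
        if len(self.control_points) < 2:
            raise ValueError("a trace needs at least 2 control points")
        steps = np.linalg.norm(np.diff(self.control_points, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive control points must be distinct")


def _format_cell(value) -> str:
    if isinstance(value, (float, np.floating)):
        return f"{value:.6f}"
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "nan"
    return str(value)


def write_particle_table(table: ParticleTable, path: str | Path) -> None:
    """Write a table as STAR (default) or TSV (``.tsv``/``.txt`` suffix)."""
    path = Path(path)
    df = table.df
    if path.suffix.lower() in (".tsv", ".txt"):
        df.to_csv(path, sep="\t", index=False)
        return
    buf = io.StringIO()
    buf.write("# helicta particle table; coordinates A, angles deg, Euler ZYZ\n")
    buf.write(f"\ndata_{_BLOCK_NAME}\n\nloop_\n")
    for i, col in enumerate(df.columns, start=1):
        buf.write(f"{_TAG_PREFIX}{col} #{i}\n")
    for _, row in df.iterrows():
        buf.write(" ".join(_format_cell(v) for v in row) + "\n")
    path.write_text(buf.getvalue())


def _read_star(path: Path) -> pd.DataFrame:
    try:
        doc = gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise TableSchemaError(f"cannot parse STAR file {path}: {exc}") from exc
    block = doc.find_block(_BLOCK_NAME) or doc.sole_block()
    cols: dict[str, list[str]] = {}
    loop = None
    for item in block:
        if item.loop is not None:
            loop = item.loop
            break
    if loop is None:
        raise TableSchemaError(f"no loop_ of particle columns found in {path}")
    for tag in loop.tags:
        name = tag[len(_TAG_PREFIX):] if tag.startswith(_TAG_PREFIX) else tag.lstrip("_")
        cols[name] = list(block.find_loop(tag))
    df = pd.DataFrame(cols)
    for c in df.columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass  # genuinely textual column
    return df


def read_particle_table(path: str | Path) -> ParticleTable:
    """Read a STAR or tab-separated particle table.

    Raises
    ------
    TableSchemaError
        If mandatory columns (see module docstring) are absent; the error
        message lists the missing names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        df = pd.read_csv(path, sep="\t")
    else:
        df = _read_star(path)
    return ParticleTable(df)


def traces_to_table(traces: list[FilamentTrace]) -> pd.DataFrame:
    """Flatten traces into a control-point DataFrame (for STAR/TSV export)."""
    rows = []
    for tr in traces:
        for j, (x, y, z) in enumerate(tr.control_points):
            rows.append(
                dict(
                    filament_id=tr.filament_id,
                    source_volume_id=tr.source_volume_id,
                    point_index=j,
                    x=x,
                    y=y,
                    z=z,
                )
            )
    return pd.DataFrame(rows)


def table_to_traces(df: pd.DataFrame) -> list[FilamentTrace]:
    traces = []
    for fid, g in df.groupby("filament_id"):
        g = g.sort_values("point_index")
        traces.append(
            FilamentTrace(
                filament_id=int(fid),
                control_points=g[["x", "y", "z"]].to_numpy(float),
                source_volume_id=int(g["source_volume_id"].iloc[0]),
            )
        )
    return traces
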