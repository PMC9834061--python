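"""Run configuration and machine-readable run records.

``RunConfig`` bundles every knob a full filament-analysis run needs, with
defaults matching the acquisition and processing settings the workflows here
emulate: 4.51 A unbinned pixels, -60..+60 deg single-axis tilt range,
60 A reference low-pass, 32.13 A intersegment distance, three refinement
iterations.  All randomness downstream flows from ``rng_seed``.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    pixel_size_unbinned: float = 4.51   # A/px at the specimen level
    binning: int = 1
    tilt_min: float = -60.0             # degrees
    tilt_max: float = 60.0
    tilt_increment: float = 2.0
    lowpass_reference: float = 60.0     # A; applied to every alignment reference
    intersegment_distance: float = 32.13  # A between consecutive segments
    n_iterations: int = 3
    rng_seed: int = 0
    box_size: int = 64                  # voxels, even

    def __post_init__(self) -> None:
        if not self.tilt_min < self.tilt_max:
            raise ValueError("tilt_min must be < tilt_max")
        if self.binning < 1 or int(self.binning) != self.binning:
            raise ValueError("binning must be an integer >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not self.lowpass_reference > 2 * self.pixel_size:
            raise ValueError(
                "lowpass_reference must exceed twice the binned pixel size "
                f"({2 * self.pixel_size:.2f} A)"
            )

    @property
    def pixel_size(self) -> float:
        """Binned pixel size in Angstrom."""
        return self.pixel_size_unbinned * self.binning

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class RunRecord:
    """Append-only log of pipeline stages and their parameters.

    Serialized as JSON so downstream tooling can reconstruct exactly what was
    run with which parameters and seed.
    """

    entries: list = field(default_factory=list)

    def log(self, stage: str, **params) -> None:
        self.entries.append(
            {"stage": stage, "time": time.time(), "params": _jsonable(params)}
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.entries, indent=2, default=str))


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
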