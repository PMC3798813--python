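"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* Image arrays are indexed ``[frame, row, col]``; row index is the axial
  (depth) direction, column index is lateral, origin at the top-left.
* Point coordinates are ``(axial, lateral)`` pairs — ``(row, col)`` in
  pixel units, ``(axial_mm, lateral_mm)`` in scene units.
* EMG samples are in microvolts; channel order is column-major over the
  electrode grid (all rows of column 0 first), with the explicit
  ``channel_map`` as the authoritative channel -> (row, col) assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import ValidationError

__all__ = [
    "GridGeometry",
    "ImageSequence",
    "EMGRecording",
    "Segmentation",
    "GroundTruth",
    "default_channel_map",
]


@dataclass(frozen=True)
class GridGeometry:
    """Electrode grid layout: 8 rows x 4 columns at 10 mm spacing by default."""

    rows: int = 8
    cols: int = 4
    ied_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValidationError("grid must have at least one row and one column")
        if self.ied_mm <= 0:
            raise ValidationError("inter-electrode distance must be positive")

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols


def default_channel_map(grid: GridGeometry) -> dict[int, tuple[int, int]]:
    """Column-major channel numbering: channel c -> (row c % rows, col c // rows)."""
    return {c: (c % grid.rows, c // grid.rows) for c in range(grid.n_channels)}


@dataclass
class ImageSequence:
    """Time-ordered stack of 8-bit grayscale frames with acquisition metadata.

    Parameters
    ----------
    frames
        ``(T, H, W)`` uint8 array.
    frame_rate_hz
        Acquisition rate, frames per second.
    calib_mm_per_px
        ``(axial, lateral)`` calibration, millimetres per pixel.
    metadata
        Free-form key/value annotations (scene description, seed, ...).
    """

    frames: np.ndarray
    frame_rate_hz: float
    calib_mm_per_px: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValidationError("frames must be a (T, H, W) stack with T >= 1")
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise ValidationError("frame intensities must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)
        if not self.frame_rate_hz > 0:
            raise ValidationError("frame_rate_hz must be positive")
        ax, lat = self.calib_mm_per_px
        if not (ax > 0 and lat > 0):
            raise ValidationError("calibration must be positive along both axes")
        self.calib_mm_per_px = (float(ax), float(lat))

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class EMGRecording:
    """Multichannel surface-EMG record (microvolts) with grid geometry and triggers."""

    samples: np.ndarray
    fs_hz: float = 2048.0
    grid: GridGeometry = field(default_factory=GridGeometry)
    trigger_samples: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    channel_map: Optional[dict[int, tuple[int, int]]] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a (channels, N) matrix")
        if self.samples.shape[0] != self.grid.n_channels:
            raise ValidationError(
                f"channel count {self.samples.shape[0]} does not match grid "
                f"{self.grid.rows} x {self.grid.cols} = {self.grid.n_channels}"
            )
        if not self.fs_hz > 0:
            raise ValidationError("fs_hz must be positive")
        trig = np.asarray(self.trigger_samples, dtype=int)
        if trig.size:
            if np.any(np.diff(trig) <= 0):
                raise ValidationError("trigger_samples must be strictly increasing")
            if trig[0] < 0 or trig[-1] >= self.samples.shape[1]:
                raise ValidationError("trigger_samples must lie within [0, N)")
        self.trigger_samples = trig
        if self.channel_map is None:
            self.channel_map = default_channel_map(self.grid)
        elif set(self.channel_map) != set(range(self.grid.n_channels)):
            raise ValidationError("channel_map must cover every channel exactly once")

    @property
    def n_channels(self) -> int:
        return int(self.samples.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channels_in_column(self, col: int) -> list[int]:
        return [c for c, (_, cc) in self.channel_map.items() if cc == col]


@dataclass
class Segmentation:
    """Aponeurosis polylines (sub-pixel px coordinates) bounding the fascicle region.

    Polylines are ``(M, 2)`` arrays of ``(row, col)`` vertices ordered by
    increasing column. The fascicle region is the band between them.
    """

    superficial: np.ndarray
    deep: np.ndarray

    def __post_init__(self) -> None:
        self.superficial = np.atleast_2d(np.asarray(self.superficial, dtype=float))
        self.deep = np.atleast_2d(np.asarray(self.deep, dtype=float))
        for name, line in (("superficial", self.superficial), ("deep", self.deep)):
            if line.shape[0] < 2 or line.shape[1] != 2:
                raise ValidationError(f"{name} polyline needs >= 2 (row, col) vertices")
            if np.any(np.diff(line[:, 1]) <= 0):
                raise ValidationError(f"{name} polyline columns must be increasing")
        lo = max(self.superficial[0, 1], self.deep[0, 1])
        hi = min(self.superficial[-1, 1], self.deep[-1, 1])
        if hi <= lo:
            raise ValidationError("polylines do not overlap laterally")
        cols = np.linspace(lo, hi, 32)
        if np.any(self.depth_at(cols, "deep") <= self.depth_at(cols, "superficial")):
            raise ValidationError("deep aponeurosis must lie strictly below superficial")

    def depth_at(self, cols: np.ndarray, which: str = "superficial") -> np.ndarray:
        """Row (depth) of a polyline at the given columns by linear interpolation."""
        line = self.superficial if which == "superficial" else self.deep
        return np.interp(np.asarray(cols, dtype=float), line[:, 1], line[:, 0])

    @property
    def lateral_extent(self) -> tuple[float, float]:
        lo = max(self.superficial[0, 1], self.deep[0, 1])
        hi = min(self.superficial[-1, 1], self.deep[-1, 1])
        return float(lo), float(hi)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of (row, col) points lying strictly between the polylines."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo, hi = self.lateral_extent
        inside_lat = (pts[:, 1] >= lo) & (pts[:, 1] <= hi)
        sup = self.depth_at(pts[:, 1], "superficial")
        deep = self.depth_at(pts[:, 1], "deep")
        return inside_lat & (pts[:, 0] > sup) & (pts[:, 0] < deep)


@dataclass
class GroundTruth:
    """Per-frame true kinematics emitted by a simulator.

    ``displacement(frame, points_mm)`` evaluates the scene's dense
    displacement field (mm) at arbitrary ``(axial, lateral)`` material
    points, i.e. positions in the frame-0 configuration.
    """

    time_s: np.ndarray
    length_mm: np.ndarray
    thickness_mm: Optional[np.ndarray] = None
    displacement: Optional[Callable[[int, np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.length_mm = np.asarray(self.length_mm, dtype=float)
        if self.length_mm.shape != self.time_s.shape:
            raise ValidationError("length series must match the time base")
        if self.thickness_mm is not None:
            self.thickness_mm = np.asarray(self.thickness_mm, dtype=float)
            if self.thickness_mm.shape != self.time_s.shape:
                raise ValidationError("thickness series must match the time base")

    @property
    def n_frames(self) -> int:
        return int(self.time_s.size)
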