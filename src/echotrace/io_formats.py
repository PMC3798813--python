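"""File formats: image sequences, EMG recordings, ground truth, config.

Image sequences travel as a multi-page TIFF plus a JSON sidecar holding the
acquisition metadata (frame rate, mm/pixel calibration, scene tags); EMG
recordings as a CSV sample matrix plus a JSON header (sampling rate, grid
geometry, trigger indices, channel map); ground truth and results tables as
CSV. Readers validate strictly and never guess: a sidecar without
calibration or a header whose channel count disagrees with the grid is a
hard error, because silent defaults would corrupt every millimetre-scale
measurement downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .containers import EMGRecording, GridGeometry, GroundTruth, ImageSequence
from .errors import SchemaError

__all__ = [
    "read_image_sequence",
    "write_image_sequence",
    "read_emg",
    "write_emg",
    "read_ground_truth",
    "write_ground_truth",
    "Config",
    "load_config",
]

PathLike = Union[str, Path]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_image_sequence(seq: ImageSequence, path: PathLike) -> Path:
    """Write frames to a multi-page TIFF and metadata to a JSON sidecar."""
    path = Path(path).with_suffix(".tif")
    tifffile.imwrite(path, seq.frames, photometric="minisblack")
    sidecar = {
        "frame_rate_hz": seq.frame_rate_hz,
        "calib_mm_per_px": list(seq.calib_mm_per_px),
        "metadata": _jsonable(seq.metadata),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_image_sequence(path: PathLike) -> ImageSequence:
    """Read a TIFF + sidecar pair written by :func:`write_image_sequence`."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise SchemaError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("frame_rate_hz", "calib_mm_per_px"):
        if key not in meta:
            raise SchemaError(f"sidecar lacks required field '{key}'")
    calib = meta["calib_mm_per_px"]
    if len(calib) != 2 or not all(c > 0 for c in calib):
        raise SchemaError("calib_mm_per_px must be two positive scalars")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageSequence(
        frames=frames,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        calib_mm_per_px=(float(calib[0]), float(calib[1])),
        metadata=meta.get("metadata", {}),
    )


#: EMG sample values are stored with fixed decimal quantization so that a
#: write -> read round trip is exact to the stored precision.
_EMG_DECIMALS = 6


def write_emg(rec: EMGRecording, path: PathLike) -> Path:
    """Write samples to CSV (one column per channel) plus a JSON header."""
    path = Path(path).with_suffix(".csv")
    np.savetxt(path, rec.samples.T, fmt=f"%.{_EMG_DECIMALS}f", delimiter=",")
    header = {
        "fs_hz": rec.fs_hz,
        "units": "uV",
        "grid": {
            "rows": rec.grid.rows,
            "cols": rec.grid.cols,
            "ied_mm": rec.grid.ied_mm,
        },
        "trigger_samples": rec.trigger_samples.tolist(),
        "channel_map": {str(ch): list(rc) for ch, rc in rec.channel_map.items()},
        "channel_order": "column-major (rows of column 0 first)",
    }
    _sidecar_path(path).write_text(json.dumps(header, indent=1))
    return path


def read_emg(path: PathLike) -> EMGRecording:
    """Read a CSV + header pair written by :func:`write_emg`."""
    path = Path(path)
    header_path = _sidecar_path(path)
    if not header_path.exists():
        raise SchemaError(f"missing header {header_path}")
    header = json.loads(header_path.read_text())
    for key in ("fs_hz", "grid", "trigger_samples"):
        if key not in header:
            raise SchemaError(f"header lacks required field '{key}'")
    g = header["grid"]
    try:
        grid = GridGeometry(rows=int(g["rows"]), cols=int(g["cols"]), ied_mm=float(g["ied_mm"]))
    except KeyError as exc:
        raise SchemaError(f"grid specification lacks {exc}") from exc
    samples = np.loadtxt(path, delimiter=",", ndmin=2).T
    if samples.shape[0] != grid.n_channels:
        raise SchemaError(
            f"data has {samples.shape[0]} channels but grid declares "
            f"{grid.rows} x {grid.cols} = {grid.n_channels}"
        )
    trig = np.asarray(header["trigger_samples"], dtype=int)
    if trig.size and np.any(np.diff(trig) <= 0):
        raise SchemaError("trigger_samples must be strictly increasing")
    cmap = None
    if "channel_map" in header:
        cmap = {int(k): (int(v[0]), int(v[1])) for k, v in header["channel_map"].items()}
    return EMGRecording(
        samples=samples, fs_hz=float(header["fs_hz"]), grid=grid,
        trigger_samples=trig, channel_map=cmap,
    )


def write_ground_truth(gt: GroundTruth, path: PathLike) -> Path:
    path = Path(path).with_suffix(".csv")
    df = pd.DataFrame(
        {
            "frame": np.arange(gt.n_frames),
            "time_s": gt.time_s,
            "length_mm": gt.length_mm,
        }
    )
    if gt.thickness_mm is not None:
        df["thickness_mm"] = gt.thickness_mm
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_ground_truth(path: PathLike) -> GroundTruth:
    df = pd.read_csv(path)
    for col in ("time_s", "length_mm"):
        if col not in df:
            raise SchemaError(f"ground-truth table lacks column '{col}'")
    return GroundTruth(
        time_s=df["time_s"].to_numpy(),
        length_mm=df["length_mm"].to_numpy(),
        thickness_mm=df["thickness_mm"].to_numpy() if "thickness_mm" in df else None,
    )


@dataclass
class Config:
    """Validated experiment configuration with protocol defaults.

    ``analysis_band_hz`` (20-450) is the M-wave analysis band; the wider
    ``acquisition_band_hz`` (10-750) mirrors the amplifier's hardware
    filter and is kept for provenance.
    """

    fs_hz: float = 2048.0
    frame_rate_hz: float = 80.0
    analysis_band_hz: tuple[float, float] = (20.0, 450.0)
    acquisition_band_hz: tuple[float, float] = (10.0, 750.0)
    filter_order: int = 4
    epoch_ms: float = 40.0
    n_epochs: int = 20
    amplifier_rms_uV: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.fs_hz <= 0:
            problems.append("fs_hz must be positive")
        if self.frame_rate_hz <= 0:
            problems.append("frame_rate_hz must be positive")
        for name in ("analysis_band_hz", "acquisition_band_hz"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                problems.append(f"{name} edges ({lo}, {hi}) must be increasing and positive")
            elif hi >= self.fs_hz / 2 and name == "analysis_band_hz":
                problems.append(f"{name} upper edge {hi} at/above Nyquist {self.fs_hz / 2}")
        if self.epoch_ms <= 0:
            problems.append("epoch_ms must be positive")
        if self.n_epochs < 1:
            problems.append("n_epochs must be at least 1")
        if self.filter_order < 1:
            problems.append("filter_order must be at least 1")
        if self.amplifier_rms_uV < 0:
            problems.append("amplifier_rms_uV must be non-negative")
        if problems:
            raise SchemaError("; ".join(problems))

    @property
    def epoch_samples(self) -> int:
        """Nearest-integer epoch length: 40 ms at 2048 Hz -> 82 samples."""
        return int(round(self.epoch_ms * self.fs_hz / 1000.0))


def load_config(path: Optional[PathLike] = None, overrides: Optional[dict] = None) -> Config:
    """Load a JSON config file, apply defaults, reject unknown keys.

    ``overrides`` (e.g. CLI flags) win over file values. An absent or empty
    file yields the full default set.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text().strip()
        if text:
            try:
                raw = json.loads(text)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"config is not valid JSON: {exc}") from exc
            if not isinstance(raw, dict):
                raise SchemaError("config must be a JSON object")
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dc_fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    for key in ("analysis_band_hz", "acquisition_band_hz"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return Config(**raw)


def _jsonable(obj):
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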