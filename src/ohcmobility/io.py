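"""Image-series and trace containers with on-disk round-trip support.

Conventions used throughout the package: 0-based pixel indices in
(row, column) order with pixel centers at integer positions; times in
seconds from the first acquired frame; physical metadata (pixel size,
frame timing) is mandatory and never defaulted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class MetadataError(ValueError):
    """Raised when required acquisition metadata is missing or inconsistent."""


@dataclass
class ImageSeries:
    """A time-ordered stack of 2-D intensity frames with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Non-negative photon counts or camera intensities.
    pixel_size_um : float
        Lateral pixel size in micrometres.
    frame_interval_s : float or None
        Uniform frame spacing in seconds. May be None only when
        ``time_offsets_s`` is given.
    bleach_frame_index : int or None
        Index of the first post-bleach frame (FRAP series only).
    time_offsets_s : ndarray or None
        Explicit per-frame acquisition times in seconds, strictly
        increasing; overrides ``frame_interval_s``. Needed for
        mixed-cadence protocols.
    ground_truth : dict
        Simulation ground truth (empty for real data).
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float | None = None
    bleach_frame_index: int | None = None
    time_offsets_s: np.ndarray | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (t, rows, cols); got ndim={self.frames.ndim}")
        if np.any(self.frames < 0):
            raise ValueError("frames must be non-negative")
        if self.pixel_size_um is None or not self.pixel_size_um > 0:
            raise MetadataError("pixel_size_um must be positive and explicit")
        if self.time_offsets_s is not None:
            self.time_offsets_s = np.asarray(self.time_offsets_s, dtype=float)
            if self.time_offsets_s.shape != (self.n_frames,):
                raise MetadataError("time_offsets_s length must match frame count")
            if np.any(np.diff(self.time_offsets_s) <= 0):
                raise MetadataError("time_offsets_s must be strictly increasing")
        elif self.frame_interval_s is None or not self.frame_interval_s > 0:
            raise MetadataError("frame_interval_s (or explicit time_offsets_s) is required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, seconds from the first frame."""
        if self.time_offsets_s is not None:
            return self.time_offsets_s
        return np.arange(self.n_frames, dtype=float) * self.frame_interval_s


def write_image_series(series: ImageSeries, tiff_path, sidecar_path=None) -> Path:
    """Write a series as multi-page TIFF (uint16 counts) plus a JSON sidecar.

    The sidecar carries all acquisition metadata and any simulation ground
    truth; by default it sits next to the TIFF with a ``.json`` suffix.
    """
    tiff_path = Path(tiff_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    data = series.frames
    if np.issubdtype(data.dtype, np.floating):
        data = np.rint(data)
    if data.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("intensities exceed the uint16 range")
    tifffile.imwrite(tiff_path, data.astype(np.uint16))
    meta = {
        "pixel_size_um": series.pixel_size_um,
        "frame_interval_s": series.frame_interval_s,
        "bleach_frame_index": series.bleach_frame_index,
        "time_offsets_s": None if series.time_offsets_s is None else list(series.time_offsets_s),
        "ground_truth": _jsonable(series.ground_truth),
    }
    sidecar_path.write_text(json.dumps(meta, indent=1))
    return tiff_path


def read_image_series(tiff_path, sidecar_path=None, require_bleach_index=False) -> ImageSeries:
    """Read a multi-page TIFF plus sidecar JSON back into an :class:`ImageSeries`.

    Missing metadata is a hard error, never defaulted.
    """
    tiff_path = Path(tiff_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise MetadataError(f"sidecar JSON not found: {sidecar_path}")
    frames = tifffile.imread(tiff_path)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise ValueError("image series needs >= 2 pages (got a single frame)")
    meta = json.loads(sidecar_path.read_text())
    if "pixel_size_um" not in meta or meta["pixel_size_um"] is None:
        raise MetadataError("sidecar missing pixel_size_um")
    offsets = meta.get("time_offsets_s")
    interval = meta.get("frame_interval_s")
    if offsets is None and interval is None:
        raise MetadataError("sidecar missing frame_interval_s and time_offsets_s")
    bleach = meta.get("bleach_frame_index")
    if require_bleach_index and bleach is None:
        raise MetadataError("sidecar missing bleach_frame_index required for FRAP input")
    return ImageSeries(
        frames=frames,
        pixel_size_um=meta["pixel_size_um"],
        frame_interval_s=interval,
        bleach_frame_index=bleach,
        time_offsets_s=None if offsets is None else np.asarray(offsets, dtype=float),
        ground_truth=meta.get("ground_truth", {}),
    )


def write_nlc_trace(voltage_mv, capacitance_pf, path) -> Path:
    path = Path(path)
    pd.DataFrame({"voltage_mV": voltage_mv, "capacitance_pF": capacitance_pf}).to_csv(
        path, index=False
    )
    return path


def read_nlc_trace(path):
    """Read a 2-column (voltage_mV, capacitance_pF) CSV."""
    df = pd.read_csv(path)
    missing = {"voltage_mV", "capacitance_pF"} - set(df.columns)
    if missing:
        raise MetadataError(f"NLC CSV missing columns: {sorted(missing)}")
    return df["voltage_mV"].to_numpy(float), df["capacitance_pF"].to_numpy(float)


def write_recovery_curve_csv(times_s, f_percent, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": times_s, "f_percent": f_percent}).to_csv(path, index=False)
    return path


def read_recovery_curve_csv(path):
    df = pd.read_csv(path)
    missing = {"time_s", "f_percent"} - set(df.columns)
    if missing:
        raise MetadataError(f"recovery-curve CSV missing columns: {sorted(missing)}")
    return df["time_s"].to_numpy(float), df["f_percent"].to_numpy(float)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
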