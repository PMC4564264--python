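"""FRAP curve extraction: ROI traces, background subtraction, acquisition-bleach
correction, and the normalized recovery curve

    f(t) = (I - I_min) / (I_max - I_min) * 100

with I the background-subtracted, reference-corrected bleach-spot mean,
I_max the mean over the first five pre-bleach scans and I_min the value at
the first post-bleach frame. Photobleach efficiency is I_min/I_max * 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ImageSeries

N_PREBLEACH_ANCHOR = 5  # normalization uses the first five pre-bleach scans


class RoiError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class CircleRoi:
    """Circular ROI; membership is center-in-circle with 0-based pixel centers."""

    center: tuple          # (row, col), pixels; need not be integral
    radius_px: float

    def mask(self, shape) -> np.ndarray:
        if self.radius_px <= 0:
            raise RoiError("ROI radius must be positive")
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        m = (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius_px ** 2
        if not m.any():
            raise RoiError("ROI contains no pixel centers")
        return m


def _as_mask(roi, shape) -> np.ndarray:
    if isinstance(roi, CircleRoi):
        return roi.mask(shape)
    m = np.asarray(roi, dtype=bool)
    if m.shape != tuple(shape):
        raise RoiError(f"mask shape {m.shape} does not match frame shape {tuple(shape)}")
    if not m.any():
        raise RoiError("empty ROI mask")
    return m


@dataclass
class RoiSet:
    """Bleach, reference, and background regions (circles or boolean masks)."""

    bleach: object
    reference: object
    background: object

    def masks(self, shape):
        b = _as_mask(self.bleach, shape)
        r = _as_mask(self.reference, shape)
        g = _as_mask(self.background, shape)
        if (b & r).any():
            raise RoiError("bleach and reference ROIs must be disjoint")
        if (g & (b | r)).any():
            raise RoiError("background ROI must be disjoint from bleach and reference")
        return b, r, g


@dataclass
class RecoveryCurve:
    """A corrected, normalized FRAP recovery curve for one cell.

    ``f_percent`` is 0 at the first post-bleach frame and averages 100
    over the five pre-bleach anchor scans by construction.
    """

    times_s: np.ndarray
    raw_i: np.ndarray          # background-subtracted bleach-ROI means
    corrected_i: np.ndarray    # after reference-ratio correction
    f_percent: np.ndarray
    i_min: float
    i_max: float
    bleach_efficiency_percent: float
    bleach_frame_index: int
    meta: dict = field(default_factory=dict)

    @property
    def post_times_s(self) -> np.ndarray:
        """Time since the bleach (0 at the first post-bleach frame)."""
        t = self.times_s[self.bleach_frame_index:]
        return t - t[0]

    @property
    def post_f_percent(self) -> np.ndarray:
        return self.f_percent[self.bleach_frame_index:]


def project_max_intensity(series: ImageSeries, group_size: int) -> ImageSeries:
    """Maximum-intensity projection of consecutive z-stacks of ``group_size`` frames.

    One output frame per group, each pixel the maximum across the group.
    The frame count must be an exact multiple of the group size.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    n = series.n_frames
    if n % group_size:
        raise ValueError(f"{n} frames do not partition into stacks of {group_size}")
    grouped = series.frames.reshape(n // group_size, group_size, *series.frames.shape[1:])
    projected = grouped.max(axis=1)
    interval = None if series.frame_interval_s is None else series.frame_interval_s * group_size
    offsets = None
    if series.time_offsets_s is not None:
        offsets = series.time_offsets_s[::group_size]
    bleach = None
    if series.bleach_frame_index is not None:
        if series.bleach_frame_index % group_size:
            raise ValueError("bleach_frame_index must fall on a group boundary")
        bleach = series.bleach_frame_index // group_size
    return ImageSeries(
        frames=projected,
        pixel_size_um=series.pixel_size_um,
        frame_interval_s=interval,
        bleach_frame_index=bleach,
        time_offsets_s=offsets,
        ground_truth=series.ground_truth,
    )


def extract_mean_trace(series: ImageSeries, roi) -> np.ndarray:
    """Per-frame arithmetic mean intensity over the ROI (circle or mask)."""
    mask = _as_mask(roi, series.frames.shape[1:])
    return series.frames[:, mask].mean(axis=1)


def correct_and_normalize(series: ImageSeries, rois: RoiSet) -> RecoveryCurve:
    """Background-subtract, correct for acquisition bleaching, and normalize.

    Steps: (i) subtract the per-frame background-ROI mean from the bleach
    and reference traces; (ii) divide the bleach trace by the reference
    trace normalized to its own five-scan pre-bleach mean — this ratio
    correction exactly cancels any multiplicative per-frame factor shared
    by the two regions; (iii) anchor I_max (pre-bleach five-scan mean) and
    I_min (first post-bleach value); (iv) normalize to percent.
    """
    if series.bleach_frame_index is None:
        raise NormalizationError("series has no bleach_frame_index")
    k = int(series.bleach_frame_index)
    if series.n_frames < 6 or k < N_PREBLEACH_ANCHOR:
        raise NormalizationError(
            f"need >= {N_PREBLEACH_ANCHOR} pre-bleach frames and at least one post-bleach frame")

    bmask, rmask, gmask = rois.masks(series.frames.shape[1:])
    bleach_tr = series.frames[:, bmask].mean(axis=1)
    ref_tr = series.frames[:, rmask].mean(axis=1)
    bg_tr = series.frames[:, gmask].mean(axis=1)

    raw = bleach_tr - bg_tr
    ref = ref_tr - bg_tr
    if np.any(ref <= 0):
        raise NormalizationError(
            "non-positive reference intensity after background subtraction")

    ref_norm = ref / ref[:N_PREBLEACH_ANCHOR].mean()
    corrected = raw / ref_norm

    i_max = corrected[:N_PREBLEACH_ANCHOR].mean()
    i_min = corrected[k]
    if i_max <= i_min:
        raise NormalizationError(
            f"degenerate bleach: I_max ({i_max:.4g}) <= I_min ({i_min:.4g})")

    f = (corrected - i_min) / (i_max - i_min) * 100.0
    return RecoveryCurve(
        times_s=series.times_s,
        raw_i=raw,
        corrected_i=corrected,
        f_percent=f,
        i_min=float(i_min),
        i_max=float(i_max),
        bleach_efficiency_percent=float(i_min / i_max * 100.0),
        bleach_frame_index=k,
        meta={"ground_truth": series.ground_truth},
    )
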