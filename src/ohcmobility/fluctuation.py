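"""Number-and-brightness fluctuation analysis.

For a photon-counting detector the counts in a pixel whose fluorophores are
fixed follow Poisson statistics, so the temporal variance equals the
temporal mean and sigma^2/mu = 1. Molecules diffusing through the detection
volume add number fluctuations on top of shot noise, pushing sigma^2/mu
above 1. The per-pixel ratio map therefore separates mobile from fixed
fluorophores without any model fitting.

No detrending is applied by default (matching the acquisition protocol the
analysis was designed for); an optional boxcar detrend exists for drifting
series but changes the Poisson calibration and is off unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import stats
from skimage.morphology import remove_small_objects
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ImageSeries


class FluctuationError(ValueError):
    pass


@dataclass
class FluctuationMap:
    """Per-pixel temporal mean, unbiased variance, and their ratio.

    ``ratio_map`` is NaN where the mean is zero (undefined, never coerced
    to 0 or 1); ``undefined_mask`` flags those pixels.
    """

    mean_map: np.ndarray
    variance_map: np.ndarray
    ratio_map: np.ndarray
    n_frames: int
    undefined_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.undefined_mask is None:
            self.undefined_mask = ~np.isfinite(self.ratio_map)

    def mean_ratio(self, mask=None) -> float:
        """Mean sigma^2/mu over defined pixels (optionally within a mask)."""
        valid = ~self.undefined_mask
        if mask is not None:
            valid = valid & np.asarray(mask, dtype=bool)
        if not valid.any():
            raise FluctuationError("no defined pixels in the requested region")
        return float(self.ratio_map[valid].mean())


class FluctuationMapper(BaseEstimator, TransformerMixin):
    """sigma^2/mu mapper over a photon-count time series, sklearn-style.

    Parameters
    ----------
    detrend_boxcar : int or None
        If set, divide each pixel series by a centered boxcar moving
        average of this (odd) width before computing moments. Off by
        default: the calibration sigma^2/mu = 1 holds for raw counts.

    Attributes
    ----------
    mean_map_, variance_map_, ratio_map_ : ndarray
        Per-pixel temporal moments (variance uses the n-1 estimator).
    n_frames_ : int
    """

    def __init__(self, detrend_boxcar=None):
        self.detrend_boxcar = detrend_boxcar

    def fit(self, X, y=None):
        frames = X.frames if isinstance(X, ImageSeries) else np.asarray(X, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 2:
            raise FluctuationError("need a (n_frames >= 2, rows, cols) stack")
        frames = frames.astype(float)
        if self.detrend_boxcar:
            w = int(self.detrend_boxcar)
            if w < 3 or w % 2 == 0:
                raise ValueError("detrend_boxcar must be an odd integer >= 3")
            kernel = np.ones(w) / w
            trend = np.apply_along_axis(
                lambda s: np.convolve(np.pad(s, w // 2, mode="edge"), kernel, "valid"),
                0, frames)
            with np.errstate(invalid="ignore", divide="ignore"):
                frames = np.where(trend > 0, frames / trend * frames.mean(axis=0), frames)
        self.mean_map_ = frames.mean(axis=0)
        self.variance_map_ = frames.var(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.ratio_map_ = np.where(
                self.mean_map_ > 0, self.variance_map_ / self.mean_map_, np.nan)
        self.n_frames_ = frames.shape[0]
        return self

    def transform(self, X):
        """Return the sigma^2/mu map of the fitted series (X is ignored)."""
        if not hasattr(self, "ratio_map_"):
            raise RuntimeError("call fit() first")
        return self.ratio_map_

    def result_(self) -> FluctuationMap:
        return FluctuationMap(
            mean_map=self.mean_map_,
            variance_map=self.variance_map_,
            ratio_map=self.ratio_map_,
            n_frames=self.n_frames_,
        )


def compute_fluctuation_map(series, detrend_boxcar=None) -> FluctuationMap:
    """Per-pixel temporal mean, unbiased variance, and sigma^2/mu ratio."""
    return FluctuationMapper(detrend_boxcar=detrend_boxcar).fit(series).result_()


def segment_regions(fmap: FluctuationMap, threshold_quantile=0.90,
                    background_quantile=0.50, min_object_px=9):
    """Quantile-threshold segmentation of the mean image into cell and background.

    Cell mask: pixels whose temporal mean exceeds the stated quantile of
    the mean image, after removal of objects smaller than
    ``min_object_px``. Background mask: pixels below ``background_quantile``.
    A hand-drawn mask can always be supplied downstream instead.
    """
    mean = fmap.mean_map
    if np.ptp(mean) == 0:
        raise FluctuationError("degenerate (constant) mean image; cannot segment")
    if not 0 < threshold_quantile < 1:
        raise FluctuationError("threshold_quantile must lie strictly in (0, 1)")
    if background_quantile >= threshold_quantile:
        raise FluctuationError("background_quantile must be below threshold_quantile")
    hi = np.quantile(mean, threshold_quantile)
    lo = np.quantile(mean, background_quantile)
    cell = remove_small_objects(mean > hi, max_size=min_object_px - 1)
    if not cell.any():
        raise FluctuationError("empty cell mask after thresholding")
    background = mean < lo
    return cell, background


@dataclass
class RegionStats:
    region_mean: float
    region_sem: float
    n_acquisitions: int
    per_acquisition: np.ndarray


@dataclass
class RegionComparison:
    cell: RegionStats
    background: RegionStats
    t_statistic: float
    p_value: float
    significant: bool


def compare_regions(maps, cell_masks, background_masks, alpha_level=0.05) -> RegionComparison:
    """Paired comparison of per-acquisition mean sigma^2/mu, cell vs background.

    One mean ratio per acquisition and region; acquisitions are the pairing
    unit of the paired t-test, as in comparing cell pixels against the
    surrounding pixels of the same recordings.
    """
    maps, cell_masks, background_masks = list(maps), list(cell_masks), list(background_masks)
    if not len(maps) == len(cell_masks) == len(background_masks):
        raise FluctuationError("maps and mask collections must have equal lengths")
    if len(maps) < 2:
        raise FluctuationError("need >= 2 acquisitions for a paired comparison")
    cell_means = np.array([m.mean_ratio(cm) for m, cm in zip(maps, cell_masks)])
    bg_means = np.array([m.mean_ratio(bm) for m, bm in zip(maps, background_masks)])
    t, p = stats.ttest_rel(cell_means, bg_means)
    n = len(maps)

    def _stats(x):
        sem = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        return RegionStats(float(x.mean()), sem, n, x)

    return RegionComparison(
        cell=_stats(cell_means),
        background=_stats(bg_means),
        t_statistic=float(t),
        p_value=float(p),
        significant=bool(p < alpha_level),
    )


def write_fluctuation_maps(fmap: FluctuationMap, out_dir, prefix="nandb") -> dict:
    """Write mu, sigma^2 and ratio maps as 32-bit float TIFFs plus a stats CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (("mean", fmap.mean_map), ("variance", fmap.variance_map),
                      ("ratio", fmap.ratio_map)):
        p = out_dir / f"{prefix}_{name}.tif"
        tifffile.imwrite(p, arr.astype(np.float32))
        paths[name] = p
    stats_path = out_dir / f"{prefix}_stats.csv"
    pd.DataFrame({
        "n_frames": [fmap.n_frames],
        "mean_ratio_full_field": [fmap.mean_ratio()],
        "n_undefined_pixels": [int(fmap.undefined_mask.sum())],
    }).to_csv(stats_path, index=False)
    paths["stats"] = stats_path
    return paths
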