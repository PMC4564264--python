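"""Synthetic microscopy and electrophysiology generators with known ground truth.

Three regimes are emulated:

* a FRAP acquisition on a membrane strip — a closed reservoir holding a
  mixture of immobile and laterally diffusing fluorophores, a circular
  bleach event, slow acquisition bleaching, and Poisson photon detection;
* a photon-counting confocal time series over fields of fixed versus
  diffusing emitters, the regime of number-and-brightness (sigma^2/mu)
  fluctuation analysis;
* a voltage–capacitance sweep following the two-state Boltzmann
  nonlinear-capacitance model with additive Gaussian noise.

Every generator takes an explicit integer seed and is bit-reproducible.
Diffusion is propagated on the fluorophore density field by per-frame
Gaussian convolution (the ensemble description the recovery models assume);
a particle-level random-walk oracle lives in the test suite only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import ImageSeries
from .nlc import NlcTrace, boltzmann_nlc


class ParameterError(ValueError):
    """Raised when simulation parameters violate their invariants."""


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

@dataclass(kw_only=True)
class FrapSimParams:
    """Parameters of the membrane-strip FRAP simulation.

    Defaults mirror the acquisition regime of the experiments the package
    analyses: 0.203 um pixels, 10 s frame interval, 5 pre-bleach scans,
    17 post-bleach scans (170 s of recovery), a 2 um bleach spot adjusted
    to remove 50-75% of fluorescence, and a mobile fraction of 0.75 with
    D = 0.1 um^2/s (tau_D = w^2/4D = 10 s) for the mobile regime.

    ``strip_rows`` bounds the membrane band (half-open row interval);
    pixels outside carry only detector background. ``photon_gain`` is the
    expected counts per unit fluorophore density per frame.
    """

    seed: int
    grid_rows: int = 128
    grid_cols: int = 128
    pixel_size_um: float = 0.203
    frame_interval_s: float = 10.0
    n_prebleach: int = 5
    n_postbleach: int = 17
    diffusion_coeff: float = 0.1          # um^2/s
    mobile_fraction: float = 0.75         # phi in [0, 1]
    bleach_center: tuple = (64, 64)       # (row, col), pixels
    bleach_radius_um: float = 2.0         # w
    bleach_depth: float = 0.6             # beta in (0, 1]
    acquisition_bleach_rate: float = 0.002  # k_acq per frame, in [0, 1)
    photon_gain: float = 100.0
    background_rate: float = 1.0          # dark counts / pixel / frame
    strip_rows: tuple = (32, 96)

    def validate(self):
        if not (0.0 <= self.mobile_fraction <= 1.0):
            raise ParameterError("mobile_fraction must lie in [0, 1]")
        if not (0.0 < self.bleach_depth <= 1.0):
            raise ParameterError("bleach_depth must lie in (0, 1]")
        if not (0.0 <= self.acquisition_bleach_rate < 1.0):
            raise ParameterError("acquisition_bleach_rate must lie in [0, 1)")
        if self.bleach_radius_um <= 0:
            raise ParameterError("bleach_radius_um must be positive")
        if self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be positive")
        if self.n_prebleach < 5:
            raise ParameterError("need >= 5 pre-bleach frames (normalization anchor)")
        if self.diffusion_coeff < 0:
            raise ParameterError("diffusion_coeff must be non-negative")
        if self.photon_gain <= 0 or self.background_rate < 0:
            raise ParameterError("photon_gain must be > 0, background_rate >= 0")
        r0, r1 = self.strip_rows
        if not (0 <= r0 < r1 <= self.grid_rows):
            raise ParameterError("strip_rows must be a valid row interval")
        w_px = self.bleach_radius_um / self.pixel_size_um
        cr, cc = self.bleach_center
        if not (r0 + w_px <= cr <= r1 - 1 - w_px and w_px <= cc <= self.grid_cols - 1 - w_px):
            raise ParameterError("bleach disc does not fit inside the membrane strip")

    @property
    def bleach_radius_px(self) -> float:
        return self.bleach_radius_um / self.pixel_size_um

    @property
    def tau_d_expected_s(self) -> float:
        """Characteristic diffusion time w^2/(4D) of the uniform-disc bleach."""
        return self.bleach_radius_um ** 2 / (4.0 * self.diffusion_coeff)


def simulate_frap_series(params: FrapSimParams) -> ImageSeries:
    """Simulate a FRAP image series and return it with ground truth attached.

    The fluorophore density on the strip is split into an immobile field
    (1 - phi) and a mobile field (phi). Between consecutive frames the
    mobile field undergoes one diffusion step — an isotropic Gaussian blur
    of standard deviation sqrt(2 D dt) per axis with reflective boundaries
    at the strip edges — and all fields decay by (1 - k_acq). The bleach
    is instantaneous at the boundary before the first post-bleach frame:
    both fields are multiplied by (1 - beta) inside the disc. Detected
    counts are Poisson with mean photon_gain x density + background_rate.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    r0, r1 = params.strip_rows
    strip_shape = (r1 - r0, params.grid_cols)

    immobile = np.full(strip_shape, 1.0 - params.mobile_fraction)
    mobile = np.full(strip_shape, params.mobile_fraction)
    sigma_px = np.sqrt(2.0 * params.diffusion_coeff * params.frame_interval_s) / params.pixel_size_um

    rr, cc = np.mgrid[r0:r1, 0:params.grid_cols]
    disc = (rr - params.bleach_center[0]) ** 2 + (cc - params.bleach_center[1]) ** 2 \
        <= params.bleach_radius_px ** 2

    n_total = params.n_prebleach + params.n_postbleach
    frames = np.empty((n_total, params.grid_rows, params.grid_cols))
    survive = 1.0 - params.acquisition_bleach_rate
    for i in range(n_total):
        if i > 0:
            if sigma_px > 0:
                mobile = gaussian_filter(mobile, sigma_px, mode="reflect")
            immobile = immobile * survive
            mobile = mobile * survive
        if i == params.n_prebleach:
            keep = np.where(disc, 1.0 - params.bleach_depth, 1.0)
            immobile = immobile * keep
            mobile = mobile * keep
        lam = np.full((params.grid_rows, params.grid_cols), params.background_rate)
        lam[r0:r1, :] += params.photon_gain * (immobile + mobile)
        frames[i] = rng.poisson(lam)

    # suggested ROIs: bleach disc, a reference spot in the strip away from
    # the disc, and a background spot outside the strip
    w_px = params.bleach_radius_px
    ref_col = (params.bleach_center[1] + params.grid_cols // 2) % params.grid_cols
    ref_col = int(np.clip(ref_col, np.ceil(w_px), params.grid_cols - 1 - np.ceil(w_px)))
    bg_row = r1 + (params.grid_rows - r1) // 2 if params.grid_rows - r1 >= r0 else r0 // 2
    gt = {
        "mobile_fraction": params.mobile_fraction,
        "diffusion_coeff_um2_s": params.diffusion_coeff,
        "tau_d_expected_s": params.tau_d_expected_s,
        "bleach_center": list(params.bleach_center),
        "bleach_radius_px": w_px,
        "bleach_depth": params.bleach_depth,
        "acquisition_bleach_rate": params.acquisition_bleach_rate,
        "strip_rows": [r0, r1],
        "roi_bleach": {"center": list(params.bleach_center), "radius_px": w_px},
        "roi_reference": {"center": [(r0 + r1) // 2, ref_col], "radius_px": w_px},
        "roi_background": {"center": [int(bg_row), params.grid_cols // 2],
                           "radius_px": min(w_px, (params.grid_rows - r1) / 2.5)},
    }
    return ImageSeries(
        frames=frames,
        pixel_size_um=params.pixel_size_um,
        frame_interval_s=params.frame_interval_s,
        bleach_frame_index=params.n_prebleach,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# Number & brightness
# ---------------------------------------------------------------------------

@dataclass(kw_only=True)
class NandbSimParams:
    """Parameters of the photon-counting fluctuation series.

    Defaults match the acquisition the analysis was designed for: 225
    frames of 256 x 256 pixels from a photon-counting detector.
    ``brightness`` is the mean detected counts per emitter per frame
    (the emitter's detection kernel integrates to 1, so the per-emitter
    expected count is exactly ``brightness``).
    """

    seed: int
    n_frames: int = 225
    grid_rows: int = 256
    grid_cols: int = 256
    n_fixed: int = 150
    n_mobile: int = 150
    brightness: float = 1.0               # epsilon, counts / emitter / frame
    step_sd: float = 1.0                  # random-walk step, pixels / frame
    psf_sd: float = 1.0                   # detection kernel sigma, pixels
    background_rate: float = 2.0          # counts / pixel / frame

    def validate(self):
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ParameterError("grid must be non-empty")
        if self.n_frames < 2:
            raise ParameterError("need >= 2 frames")
        if min(self.n_fixed, self.n_mobile) < 0:
            raise ParameterError("emitter counts must be >= 0")
        if self.brightness < 0 or self.background_rate < 0:
            raise ParameterError("brightness and background_rate must be >= 0")
        if self.step_sd < 0 or self.psf_sd <= 0:
            raise ParameterError("step_sd >= 0 and psf_sd > 0 required")


def _add_emitters(lam, positions, eps, psf_sd):
    """Add normalized Gaussian detection kernels at continuous positions.

    Periodic boundaries; each kernel is renormalized over its support so
    every emitter contributes exactly ``eps`` expected counts per frame.
    """
    nr, nc = lam.shape
    half = int(np.ceil(4 * psf_sd))
    offs = np.arange(-half, half + 1)
    for r, c in positions:
        rows = (int(np.round(r)) + offs) % nr
        cols = (int(np.round(c)) + offs) % nc
        dr = (int(np.round(r)) + offs) - r
        dc = (int(np.round(c)) + offs) - c
        k = np.exp(-0.5 * (dr[:, None] ** 2 + dc[None, :] ** 2) / psf_sd ** 2)
        lam[np.ix_(rows, cols)] += eps * k / k.sum()


def _occupancy_mask(shape, positions, radius):
    mask = np.zeros(shape, dtype=bool)
    if len(positions) == 0:
        return mask
    nr, nc = shape
    half = int(np.ceil(radius))
    offs = np.arange(-half, half + 1)
    for r, c in positions:
        rows = (int(np.round(r)) + offs) % nr
        cols = (int(np.round(c)) + offs) % nc
        dr = (int(np.round(r)) + offs) - r
        dc = (int(np.round(c)) + offs) - c
        mask[np.ix_(rows, cols)] |= dr[:, None] ** 2 + dc[None, :] ** 2 <= radius ** 2
    return mask


def simulate_nandb_series(
    params: NandbSimParams,
    fixed_positions: np.ndarray | None = None,
    mobile_start: np.ndarray | None = None,
) -> ImageSeries:
    """Simulate a photon-counting confocal time series of fixed and mobile emitters.

    Each frame: mobile emitters take one isotropic Gaussian random-walk step
    (periodic boundaries), every emitter deposits a normalized Gaussian
    kernel of width ``psf_sd``, and per-pixel counts are Poisson with mean
    background_rate + brightness x (summed kernel weights). Ground-truth
    occupancy masks (pixels within 2 psf_sd of any fixed emitter, and of any
    mobile-emitter position over the whole trajectory) ride along in
    ``ground_truth``. Emitter start positions are uniform unless supplied.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = (params.grid_rows, params.grid_cols)

    if fixed_positions is None:
        fixed_positions = rng.uniform((0, 0), shape, size=(params.n_fixed, 2))
    else:
        fixed_positions = np.asarray(fixed_positions, dtype=float).reshape(-1, 2)
    if mobile_start is None:
        mobile = rng.uniform((0, 0), shape, size=(params.n_mobile, 2))
    else:
        mobile = np.asarray(mobile_start, dtype=float).reshape(-1, 2).copy()

    fixed_lam = np.zeros(shape)
    _add_emitters(fixed_lam, fixed_positions, params.brightness, params.psf_sd)

    frames = np.empty((params.n_frames,) + shape)
    trajectory = np.empty((params.n_frames, len(mobile), 2))
    for t in range(params.n_frames):
        if t > 0 and len(mobile):
            mobile = (mobile + rng.normal(0, params.step_sd, mobile.shape)) % shape
        trajectory[t] = mobile
        lam = fixed_lam + params.background_rate
        if len(mobile):
            lam = lam.copy()
            _add_emitters(lam, mobile, params.brightness, params.psf_sd)
        frames[t] = rng.poisson(lam)

    visited = trajectory.reshape(-1, 2)
    gt = {
        "fixed_positions": fixed_positions,
        "mobile_trajectory": trajectory,
        "fixed_mask": _occupancy_mask(shape, fixed_positions, 2 * params.psf_sd),
        "mobile_mask": _occupancy_mask(shape, visited, 2 * params.psf_sd),
        "brightness": params.brightness,
        "background_rate": params.background_rate,
    }
    # frame time = one full raster of the field; nominal line frequency 100 Hz
    return ImageSeries(
        frames=frames,
        pixel_size_um=0.1,
        frame_interval_s=params.grid_rows / 100.0,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# Nonlinear capacitance
# ---------------------------------------------------------------------------

@dataclass(kw_only=True)
class NlcSimParams:
    """Two-state Boltzmann NLC trace parameters.

    Consistent unit convention: capacitance in pF, voltage in mV and Qmax
    in fC, so that the NLC integrates over voltage to exactly Qmax.
    Defaults are typical of a healthy outer hair cell: Qmax 750 fC,
    alpha 0.035 /mV, Vh -70 mV, Clin 7 pF.
    """

    seed: int
    qmax: float = 750.0                   # fC
    alpha: float = 0.035                  # 1/mV
    vh: float = -70.0                     # mV
    clin: float = 7.0                     # pF
    voltage_grid: np.ndarray = field(
        default_factory=lambda: np.arange(-150.0, 50.0 + 1e-9, 2.5))
    noise_sd: float = 0.13                # pF, ~2% of peak NLC at defaults

    def validate(self):
        if self.qmax <= 0 or self.alpha <= 0:
            raise ParameterError("qmax and alpha must be positive")
        v = np.asarray(self.voltage_grid, dtype=float)
        if v.ndim != 1 or len(v) < 8 or np.any(np.diff(v) <= 0):
            raise ParameterError("voltage_grid must be strictly increasing with >= 8 points")
        if not (v[0] < self.vh < v[-1]):
            raise ParameterError("voltage_grid must span Vh")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def simulate_nlc_trace(params: NlcSimParams) -> NlcTrace:
    """Simulate a voltage–capacitance sweep with Gaussian noise; truth attached."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    v = np.asarray(params.voltage_grid, dtype=float)
    c = boltzmann_nlc(v, params.qmax, params.alpha, params.vh, params.clin)
    c = c + rng.normal(0.0, params.noise_sd, size=v.shape)
    return NlcTrace(
        voltage_mv=v,
        capacitance_pf=c,
        ground_truth={"qmax": params.qmax, "alpha": params.alpha,
                      "vh": params.vh, "clin": params.clin},
    )
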