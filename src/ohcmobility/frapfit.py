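"""Recovery-curve models and fitting.

Two models for the normalized recovery fraction f(t) (on the 0–1 scale):

* the Axelrod/Soumpasis uniform-disc diffusion model

      f(t) = A exp(-2 tau_D / t) [I0(2 tau_D / t) + I1(2 tau_D / t)],

  with A the mobile fraction, tau_D = w^2/(4D) the characteristic
  diffusion time of a bleach spot of radius w, and I0, I1 modified Bessel
  functions of the first kind; f(0) = 0 and f(t) -> A as t -> infinity;

* a saturating single exponential f(t) = A (1 - exp(-k t)) for curves the
  diffusion model does not describe.

Fitting uses nonlinear least squares on post-bleach points only, with
multi-start initialization and explicit bounds. A repeated-measures
decision rule tests whether a population of cells shows significant
recovery between the immediate post-bleach bin and a late-time bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .frap import RecoveryCurve

_A_STARTS = (0.25, 0.5, 0.9)
_SCALE_STARTS = (0.1, 0.5, 1.0)   # times the post-bleach time span


class FitInputError(ValueError):
    pass


def eval_axelrod(A, tau_d, t):
    """Axelrod/Soumpasis recovery model; vectorized in t, 0 at t = 0."""
    if np.any(np.asarray(tau_d) <= 0):
        raise ValueError("tau_d must be positive")
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast_shapes(t.shape, np.shape(A), np.shape(tau_d)))
    pos = t > 0
    with np.errstate(divide="ignore"):
        x = np.where(pos, 2.0 * tau_d / np.where(pos, t, 1.0), np.inf)
    # i0e/i1e are exp(-x) I0(x), exp(-x) I1(x): stable for large x
    vals = A * (special.i0e(x[pos]) + special.i1e(x[pos]))
    if out.ndim == 0:
        return float(vals[0]) if pos else 0.0
    out[pos] = vals
    return out


def eval_single_exp(A, k, t):
    """Saturating single-exponential recovery A (1 - exp(-k t))."""
    if np.any(np.asarray(k) <= 0):
        raise ValueError("k must be positive")
    t = np.asarray(t, dtype=float)
    return A * (1.0 - np.exp(-k * t))


@dataclass
class FrapFit:
    """Result of fitting one recovery curve.

    Exactly one of ``tau_d_s``/``k_per_s`` is set, matching ``model``.
    ``A`` is the mobile fraction on the 0–1 scale of f/100.
    """

    model: str
    A: float
    tau_d_s: float | None
    k_per_s: float | None
    residual_ss: float
    converged: bool
    covariance: np.ndarray | None = None
    n_points: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def timescale_s(self) -> float:
        return self.tau_d_s if self.model == "axelrod" else 1.0 / self.k_per_s

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "A": self.A,
            "tau_D_s": self.tau_d_s,
            "k_per_s": self.k_per_s,
            "residual_ss": self.residual_ss,
            "converged": self.converged,
        }


class FrapRecoveryModel(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares recovery-curve fitter, sklearn-style.

    Parameters
    ----------
    model : {"axelrod", "single_exponential"}
        Functional form for f(t) on the 0–1 scale.
    a_max : float
        Upper bound on the mobile fraction (default 1.2 tolerates
        normalization overshoot).
    timescale_max_factor : float
        Upper bound on tau_D (or 1/k) as a multiple of the post-bleach
        time span.

    Attributes
    ----------
    mobile_fraction_ : float
        Fitted A.
    tau_d_ : float or None
        Fitted diffusion timescale, s (axelrod model).
    rate_ : float or None
        Fitted rate constant, 1/s (single-exponential model).
    residual_ss_, converged_, covariance_ : fit diagnostics.
    """

    def __init__(self, model="axelrod", a_max=1.2, timescale_max_factor=100.0):
        self.model = model
        self.a_max = a_max
        self.timescale_max_factor = timescale_max_factor

    def _eval(self, t, A, scale):
        if self.model == "axelrod":
            return eval_axelrod(A, scale, t)
        return eval_single_exp(A, 1.0 / scale, t)

    def fit(self, t, f):
        """Fit post-bleach points (t in seconds since bleach, f on 0–1 scale)."""
        if self.model not in ("axelrod", "single_exponential"):
            raise ValueError(f"unknown model {self.model!r}")
        t = np.asarray(t, dtype=float).ravel()
        f = np.asarray(f, dtype=float).ravel()
        if t.shape != f.shape:
            raise FitInputError("t and f must have the same length")
        if len(t) < 8:
            raise FitInputError("need >= 8 post-bleach points to fit")
        span = float(t.max() - t.min())
        if span <= 0:
            raise FitInputError("post-bleach times are degenerate")

        bounds = ([0.0, 1e-9], [self.a_max, self.timescale_max_factor * span])
        best = None
        for a0 in _A_STARTS:
            for s0 in _SCALE_STARTS:
                try:
                    popt, pcov = optimize.curve_fit(
                        self._eval, t, f, p0=[a0, s0 * span],
                        bounds=bounds, maxfev=20000)
                except (RuntimeError, optimize.OptimizeWarning):
                    continue
                ss = float(np.sum((self._eval(t, *popt) - f) ** 2))
                if best is None or ss < best[0]:
                    best = (ss, popt, pcov)

        if best is None:
            self.mobile_fraction_ = np.nan
            self.tau_d_ = self.rate_ = None
            self.residual_ss_ = np.inf
            self.converged_ = False
            self.covariance_ = None
            self.n_points_ = len(t)
            return self

        ss, popt, pcov = best
        self.mobile_fraction_ = float(popt[0])
        if self.model == "axelrod":
            self.tau_d_, self.rate_ = float(popt[1]), None
        else:
            self.tau_d_, self.rate_ = None, float(1.0 / popt[1])
        self.residual_ss_ = ss
        self.converged_ = True
        self.covariance_ = pcov
        self.n_points_ = len(t)
        return self

    def predict(self, t):
        if not hasattr(self, "converged_"):
            raise RuntimeError("call fit() first")
        scale = self.tau_d_ if self.model == "axelrod" else 1.0 / self.rate_
        return self._eval(np.asarray(t, dtype=float), self.mobile_fraction_, scale)

    def result_(self) -> FrapFit:
        return FrapFit(
            model=self.model,
            A=self.mobile_fraction_,
            tau_d_s=self.tau_d_,
            k_per_s=self.rate_,
            residual_ss=self.residual_ss_,
            converged=self.converged_,
            covariance=self.covariance_,
            n_points=self.n_points_,
        )


def fit_recovery(curve: RecoveryCurve, model: str = "axelrod") -> FrapFit:
    """Fit one normalized recovery curve (post-bleach points only, f/100)."""
    est = FrapRecoveryModel(model=model)
    est.fit(curve.post_times_s, curve.post_f_percent / 100.0)
    return est.result_()


def tau_to_diffusion_coeff(tau_d_s: float, bleach_radius_um: float) -> float:
    """Convenience conversion D = w^2 / (4 tau_D) for a uniform disc bleach.

    Provided for completeness; not part of the analysis pipeline proper.
    """
    if tau_d_s <= 0 or bleach_radius_um <= 0:
        raise ValueError("tau_d_s and bleach_radius_um must be positive")
    return bleach_radius_um ** 2 / (4.0 * tau_d_s)


@dataclass
class SignificanceResult:
    statistic_f: float
    p_value: float
    significant: bool
    n_cells: int
    early_means: np.ndarray
    late_means: np.ndarray


def recovery_significance(
    curves,
    window_late_s=(150.0, 170.0),
    alpha_level=0.05,
    n_early=3,
) -> SignificanceResult:
    """Decide whether a population of cells shows significant recovery.

    Within each cell the normalized f is averaged over the immediate
    post-bleach bin (first ``n_early`` post-bleach points) and over the
    late bin (points with post-bleach time inside ``window_late_s``); the
    two bins are compared across cells by a repeated-measures test (two
    paired levels, so F = t^2 of the paired t-test).
    """
    curves = list(curves)
    if len(curves) < 3:
        raise FitInputError("need >= 3 cells for the recovery decision")
    early, late = [], []
    for c in curves:
        t = c.post_times_s
        f = c.post_f_percent
        sel = (t >= window_late_s[0]) & (t <= window_late_s[1])
        if not sel.any():
            raise FitInputError(
                f"late window {window_late_s} contains no post-bleach points")
        early.append(f[:n_early].mean())
        late.append(f[sel].mean())
    early = np.asarray(early)
    late = np.asarray(late)
    tstat, p = stats.ttest_rel(late, early)
    return SignificanceResult(
        statistic_f=float(tstat ** 2),
        p_value=float(p),
        significant=bool(p < alpha_level),
        n_cells=len(curves),
        early_means=early,
        late_means=late,
    )
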