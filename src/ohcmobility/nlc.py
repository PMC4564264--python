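"""Nonlinear-capacitance Boltzmann fitting and lateral-wall morphometry.

The voltage-dependent (nonlinear) membrane capacitance of an outer hair
cell is the derivative of a two-state Boltzmann charge transfer:

    C(V) = Clin + Qmax * alpha * b / (1 + b)^2,   b = exp(-alpha (V - Vh)),

with Qmax the total mobile charge, alpha the voltage sensitivity (which
absorbs zF/RT of the valence form), Vh the voltage of peak capacitance and
Clin the linear (geometric) capacitance. The NLC is bell-shaped, symmetric
about Vh, peaks at Clin + Qmax*alpha/4 and integrates over voltage to
exactly Qmax. Consistent units: capacitance pF, voltage mV, charge fC.

Morphometry reduces to the cylinder lateral-surface formula
A_lat = pi * D * L from user-supplied length and diameter measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin


class NlcError(ValueError):
    pass


def boltzmann_nlc(v, qmax, alpha, vh, clin):
    """Two-state Boltzmann NLC evaluated at voltage(s) v."""
    b = np.exp(-alpha * (np.asarray(v, dtype=float) - vh))
    return clin + qmax * alpha * b / (1.0 + b) ** 2


@dataclass
class NlcTrace:
    """An ordered voltage–capacitance sweep."""

    voltage_mv: np.ndarray
    capacitance_pf: np.ndarray
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=float)
        self.capacitance_pf = np.asarray(self.capacitance_pf, dtype=float)
        if self.voltage_mv.shape != self.capacitance_pf.shape:
            raise NlcError("voltage and capacitance must have equal lengths")
        if len(self.voltage_mv) < 8:
            raise NlcError("need >= 8 sweep points")
        d = np.diff(self.voltage_mv)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise NlcError("voltage must be strictly monotone")


@dataclass
class NlcFit:
    qmax: float            # fC
    alpha: float           # 1/mV
    vh: float              # mV
    clin: float            # pF
    residual_ss: float
    converged: bool
    peak_at_edge: bool = False
    covariance: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {"Qmax_fC": self.qmax, "alpha_per_mV": self.alpha, "Vh_mV": self.vh,
                "Clin_pF": self.clin, "residual_ss": self.residual_ss,
                "converged": self.converged, "peak_at_edge": self.peak_at_edge}


class BoltzmannNLCModel(BaseEstimator, RegressorMixin):
    """Least-squares Boltzmann NLC fitter, sklearn-style.

    Initialization: Clin from the minimum capacitance, Vh from the
    capacitance peak, alpha = 0.03 /mV (typical prestin sensitivity),
    Qmax = 4 (peak - Clin)/alpha from the peak identity. All parameters
    bounded positive (Vh unbounded).

    Attributes: ``qmax_``, ``alpha_``, ``vh_``, ``clin_``,
    ``residual_ss_``, ``converged_``, ``peak_at_edge_``, ``covariance_``.
    """

    def __init__(self, alpha_init=0.03):
        self.alpha_init = alpha_init

    def fit(self, v, c):
        v = np.asarray(v, dtype=float).ravel()
        c = np.asarray(c, dtype=float).ravel()
        if v.shape != c.shape or len(v) < 8:
            raise NlcError("need matched voltage/capacitance arrays with >= 8 points")
        ipk = int(np.argmax(c))
        self.peak_at_edge_ = ipk in (0, len(c) - 1)
        clin0 = float(c.min())
        vh0 = float(v[ipk])
        a0 = self.alpha_init
        q0 = max(4.0 * (float(c[ipk]) - clin0) / a0, 1e-6)
        bounds = ([1e-9, 1e-6, -np.inf, 1e-9], [np.inf, 1.0, np.inf, np.inf])
        try:
            popt, pcov = optimize.curve_fit(
                boltzmann_nlc, v, c, p0=[q0, a0, vh0, max(clin0, 1e-6)],
                bounds=bounds, maxfev=20000)
            self.converged_ = True
        except RuntimeError:
            popt = [q0, a0, vh0, max(clin0, 1e-6)]
            pcov = None
            self.converged_ = False
        self.qmax_, self.alpha_, self.vh_, self.clin_ = map(float, popt)
        self.covariance_ = pcov
        self.residual_ss_ = float(np.sum((boltzmann_nlc(v, *popt) - c) ** 2))
        return self

    def predict(self, v):
        if not hasattr(self, "qmax_"):
            raise RuntimeError("call fit() first")
        return boltzmann_nlc(v, self.qmax_, self.alpha_, self.vh_, self.clin_)

    def result_(self) -> NlcFit:
        return NlcFit(
            qmax=self.qmax_, alpha=self.alpha_, vh=self.vh_, clin=self.clin_,
            residual_ss=self.residual_ss_, converged=self.converged_,
            peak_at_edge=self.peak_at_edge_, covariance=self.covariance_,
        )


def fit_boltzmann_nlc(trace: NlcTrace) -> NlcFit:
    """Fit C(V) = Clin + Qmax alpha b/(1+b)^2 to a voltage–capacitance sweep."""
    return BoltzmannNLCModel().fit(trace.voltage_mv, trace.capacitance_pf).result_()


def relative_qmax(group, reference):
    """Group-mean Qmax as percent of the reference-group mean, with SEM.

    SEM by first-order (delta-method) propagation of the two group SEMs.
    Returns ``(percent, sem_percent)``.
    """
    g = np.array([f.qmax for f in group], dtype=float)
    r = np.array([f.qmax for f in reference], dtype=float)
    if len(g) == 0 or len(r) == 0:
        raise NlcError("both fit collections must be non-empty")
    ratio = g.mean() / r.mean()
    sem_g = g.std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else 0.0
    sem_r = r.std(ddof=1) / np.sqrt(len(r)) if len(r) > 1 else 0.0
    sem = ratio * np.sqrt((sem_g / g.mean()) ** 2 + (sem_r / r.mean()) ** 2)
    return 100.0 * ratio, 100.0 * sem


@dataclass(frozen=True)
class OhcGeometry:
    """Cylindrical lateral-wall geometry of one outer hair cell."""

    length_um: float
    diameter_um: float

    @property
    def lateral_area_um2(self) -> float:
        return lateral_area(self.diameter_um, self.length_um)


def lateral_area(diameter_um: float, length_um: float) -> float:
    """Lateral membrane area of a cylinder: A_lat = pi * D * L."""
    if diameter_um <= 0 or length_um <= 0:
        raise ValueError("diameter and length must be positive")
    return np.pi * diameter_um * length_um
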