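"""Nucleated-patch geometry and proton-gated current kinetics.

Covers the channel-biophysics arithmetic of the pipeline:

* membrane area and capacitance of a nucleated patch modelled as a prolate
  spheroid (specific capacitance 1 uF/cm^2);
* peak current and current density (pA/pF) from a voltage-clamp sweep;
* single-exponential desensitization fit  I(t) = A exp(-t/tau) + C;
* Hill fit of the pH-response curve in proton concentration,
  R(c) = A / (1 + (EC50/c)^n) with c = 10^(-pH);
* second-order-polynomial interpolation of the reversal potential from an
  I-V table, with the Nernst potential as the theoretical reference;
* single-exponential tachyphylaxis (cumulative run-down) fit across
  repeated agonist applications.

The three nonlinear fits are exposed both as small sklearn-style
estimators (`ExponentialDecay`, `HillCurve`, `QuadraticIV`) and as the
module-level functions that the rest of the pipeline calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .sweeps import SweepRecording

__all__ = [
    "PatchGeometry",
    "ASICMetrics",
    "DesensFit",
    "HillFit",
    "ReversalFit",
    "NernstParams",
    "TachyFit",
    "ExponentialDecay",
    "HillCurve",
    "QuadraticIV",
    "patch_capacitance",
    "current_density",
    "fit_desensitization",
    "fit_hill_ph",
    "fit_reversal",
    "nernst_potential",
    "fit_tachyphylaxis",
]

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol
SPECIFIC_CAPACITANCE_PF_PER_UM2 = 0.01  # 1 uF/cm^2


# --------------------------------------------------------------------------
# patch geometry


@dataclass
class PatchGeometry:
    """Ellipsoid-approximated nucleated patch: axes, area, capacitance."""

    minor_um: float
    major_um: float
    area_um2: float
    capacitance_pf: float


def _prolate_area(minor_um: float, major_um: float) -> float:
    # semi-axes; a >= b, spheroid of revolution about the major axis
    a = major_um / 2.0
    b = minor_um / 2.0
    if a == b:
        return 4.0 * math.pi * a * a
    e = math.sqrt(1.0 - (b * b) / (a * a))
    return 2.0 * math.pi * b * b + 2.0 * math.pi * a * b * math.asin(e) / e


def _thomsen_area(minor_um: float, major_um: float, p: float = 1.6075) -> float:
    # Knud Thomsen approximation with two equal equatorial semi-axes
    a = major_um / 2.0
    b = c = minor_um / 2.0
    term = (a**p * b**p + a**p * c**p + b**p * c**p) / 3.0
    return 4.0 * math.pi * term ** (1.0 / p)


def patch_capacitance(minor_um: float, major_um: float, method: str = "prolate") -> PatchGeometry:
    """Surface area and capacitance of a nucleated patch.

    The patch is modelled as a prolate spheroid with the measured minor
    and major axes (full axes, um).  ``method="thomsen"`` switches to the
    Knud Thomsen general-ellipsoid approximation.  Capacitance assumes a
    specific membrane capacitance of 1 uF/cm^2 (0.01 pF/um^2).
    """
    if not (0.0 < minor_um <= major_um):
        raise ValueError(
            f"need 0 < minor <= major; got minor={minor_um}, major={major_um} "
            "(axes may be swapped)"
        )
    if method == "prolate":
        area = _prolate_area(minor_um, major_um)
    elif method == "thomsen":
        area = _thomsen_area(minor_um, major_um)
    else:
        raise ValueError(f"unknown area method {method!r}")
    return PatchGeometry(minor_um, major_um, area, area * SPECIFIC_CAPACITANCE_PF_PER_UM2)


# --------------------------------------------------------------------------
# fitted-record types


@dataclass
class DesensFit:
    """A exp(-t/tau) + C fitted from the current peak to pulse end."""

    amplitude_pa: float
    tau_ms: float
    steady_pa: float
    rms_pa: float
    converged: bool
    reason: Optional[str] = None


@dataclass
class ASICMetrics:
    """Per-patch channel metrics from one agonist application."""

    peak_pa: float
    density_pa_per_pf: float
    capacitance_pf: float
    ph: Optional[float] = None
    holding_mv: Optional[float] = None
    desensitization: Optional[DesensFit] = None


@dataclass
class HillFit:
    """Hill law in proton concentration; reported on the pH scale too."""

    amax: float
    ph50: float
    hill_n: float
    rms: float = 0.0
    converged: bool = True

    @property
    def ec50_molar(self) -> float:
        return 10.0 ** (-self.ph50)

    def predict(self, ph) -> np.ndarray:
        c = 10.0 ** (-np.asarray(ph, dtype=float))
        return self.amax / (1.0 + (self.ec50_molar / c) ** self.hill_n)


@dataclass
class ReversalFit:
    coefficients: tuple  # quadratic, highest order first
    vrev_mv: float
    span_mv: tuple


@dataclass
class NernstParams:
    na_out_mm: float
    na_in_mm: float
    temperature_k: float = 298.0


@dataclass
class TachyFit:
    amplitude: float
    tau_s: float
    plateau: float
    rms: float
    converged: bool
    reason: Optional[str] = None


# --------------------------------------------------------------------------
# sklearn-style curve estimators


class ExponentialDecay(BaseEstimator, RegressorMixin):
    """Least-squares fit of y(t) = a exp(-t/tau) + c.

    The decay time is initialised from the first 1/e crossing of the
    detrended data and refined by bounded trust-region least squares.

    Attributes (after ``fit``): ``amplitude_``, ``tau_``, ``offset_``,
    ``rms_``, ``converged_``.
    """

    def __init__(self, tol: float = 1e-10, max_tau_factor: float = 1e3):
        self.tol = tol
        self.max_tau_factor = max_tau_factor

    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.size != y.size or t.size < 3:
            raise ValueError("need >= 3 (t, y) points")
        span = t[-1] - t[0]
        if span <= 0:
            raise ValueError("t must be increasing")
        c0 = y[-1]
        a0 = y[0] - c0
        self.converged_ = True
        self.reason_ = None
        if a0 == 0.0 or abs(a0) < 1e-12 * max(1.0, abs(c0)):
            # flat input: nothing to fit
            self.amplitude_, self.tau_, self.offset_ = 0.0, math.nan, float(np.mean(y))
            self.rms_ = float(np.sqrt(np.mean((y - np.mean(y)) ** 2)))
            self.converged_ = False
            self.reason_ = "no decay to fit"
            return self
        # tau0 from the first crossing of a0/e above the final level
        target = c0 + a0 / math.e
        crossed = np.nonzero((y - target) * np.sign(a0) <= 0)[0]
        tau0 = (t[crossed[0]] - t[0]) if crossed.size else span / 3.0
        tau0 = min(max(tau0, span * 1e-3), span * self.max_tau_factor)

        def resid(p):
            a, tau, c = p
            return a * np.exp(-(t - t[0]) / tau) + c - y

        hi_tau = span * self.max_tau_factor
        sol = least_squares(
            resid,
            x0=[a0, tau0, c0],
            bounds=([-np.inf, span * 1e-6, -np.inf], [np.inf, hi_tau, np.inf]),
            xtol=self.tol, ftol=self.tol, gtol=self.tol,
        )
        self.amplitude_, self.tau_, self.offset_ = map(float, sol.x)
        self.rms_ = float(np.sqrt(np.mean(sol.fun**2)))
        if self.tau_ >= hi_tau * 0.99:
            self.converged_ = False
            self.reason_ = "decay time unbounded (non-decaying trace)"
        self.t0_ = float(t[0])
        return self

    def predict(self, t):
        t = np.asarray(t, dtype=float).ravel()
        return self.amplitude_ * np.exp(-(t - self.t0_) / self.tau_) + self.offset_


class HillCurve(BaseEstimator, RegressorMixin):
    """Hill-law dose-response fit in proton concentration.

    Model: R(pH) = A / (1 + (EC50 / c)^n), c = 10^(-pH).  Parameters are
    fitted as (A, pH50, n) with pH50 = -log10(EC50), which is numerically
    better conditioned than fitting EC50 in molar; the two
    parameterizations give identical predictions.

    Attributes: ``amax_``, ``ph50_``, ``hill_n_``, ``rms_``, ``converged_``.
    """

    def __init__(self, tol: float = 1e-10, max_residual: float = 0.15):
        self.tol = tol
        self.max_residual = max_residual

    def fit(self, ph, response):
        ph = np.asarray(ph, dtype=float).ravel()
        response = np.asarray(response, dtype=float).ravel()
        if np.unique(ph).size < 4:
            raise ValueError("need >= 4 distinct pH values spanning the transition")
        a0 = float(np.max(response))
        if a0 <= 0:
            raise ValueError("responses must contain positive values")
        half = a0 / 2.0
        ph50_0 = float(ph[np.argmin(np.abs(response - half))])

        def resid(p):
            a, ph50, n = p
            c = 10.0 ** (-ph)
            return a / (1.0 + (10.0 ** (-ph50) / c) ** n) - response

        sol = least_squares(
            resid,
            x0=[a0, ph50_0, 1.0],
            bounds=([1e-9, 3.0, 1e-3], [np.inf, 9.0, 20.0]),
            xtol=self.tol, ftol=self.tol, gtol=self.tol,
        )
        self.amax_, self.ph50_, self.hill_n_ = map(float, sol.x)
        self.rms_ = float(np.sqrt(np.mean(sol.fun**2)))
        # gross monotonicity violations show up as large lack of fit
        self.converged_ = bool(self.rms_ <= self.max_residual * max(a0, 1e-12))
        return self

    def predict(self, ph):
        c = 10.0 ** (-np.asarray(ph, dtype=float).ravel())
        return self.amax_ / (1.0 + (10.0 ** (-self.ph50_) / c) ** self.hill_n_)


class QuadraticIV(BaseEstimator, RegressorMixin):
    """Second-order polynomial I-V fit with in-span zero crossing.

    Attributes: ``coefficients_`` (highest order first), ``vrev_`` (mV).
    """

    def fit(self, v, i):
        v = np.asarray(v, dtype=float).ravel()
        i = np.asarray(i, dtype=float).ravel()
        if v.size < 4:
            raise ValueError("need >= 4 I-V points")
        if np.min(i) > 0 or np.max(i) < 0:
            raise ValueError("no sign change of I within the voltage span")
        coeffs = np.polyfit(v, i, 2)
        span = (float(v.min()), float(v.max()))
        a2, a1, a0 = coeffs
        if abs(a2) < 1e-12 * max(abs(a1), 1.0):
            roots = np.array([-a0 / a1])
        else:
            roots = np.roots(coeffs)
        real = roots[np.abs(np.imag(roots)) < 1e-8].real
        in_span = real[(real >= span[0] - 1e-9) & (real <= span[1] + 1e-9)]
        if in_span.size == 0:
            raise ValueError(
                f"no real root inside the data span {span}; roots at {np.sort(real)}"
            )
        # nearest to the observed sign change
        sign_flip = np.nonzero(np.diff(np.sign(i)))[0]
        v_flip = v[sign_flip[0]] if sign_flip.size else 0.5 * (span[0] + span[1])
        self.vrev_ = float(in_span[np.argmin(np.abs(in_span - v_flip))])
        self.coefficients_ = tuple(map(float, coeffs))
        self.span_ = span
        return self

    def predict(self, v):
        return np.polyval(self.coefficients_, np.asarray(v, dtype=float).ravel())


# --------------------------------------------------------------------------
# module-level operations


def current_density(
    sweep: SweepRecording,
    geometry: PatchGeometry,
    direction: str = "inward",
    fit_desens: bool = False,
) -> ASICMetrics:
    """Peak current and current density of a proton-evoked response.

    The peak is the signed extremum within the agonist pulse, measured
    relative to the pre-pulse baseline (``direction="inward"`` takes the
    minimum, matching Na+ influx at negative holding potentials).
    Density is \\|peak\\| / capacitance in pA/pF.
    """
    if sweep.clamp != "voltage":
        raise TypeError("current density requires a voltage-clamp sweep")
    if sweep.pulse_window is None:
        raise ValueError("sweep lacks pulse metadata")
    if geometry.capacitance_pf <= 0:
        raise ValueError("capacitance must be positive")
    pre = sweep.time_s < sweep.pulse_window[0]
    baseline = float(np.mean(sweep.samples[pre])) if pre.any() else 0.0
    in_pulse = sweep.window_mask(sweep.pulse_window)
    rel = sweep.samples[in_pulse] - baseline
    if direction == "inward":
        peak = float(np.min(rel))
    elif direction == "outward":
        peak = float(np.max(rel))
    else:
        raise ValueError("direction must be 'inward' or 'outward'")
    desens = fit_desensitization(sweep, direction=direction) if fit_desens else None
    return ASICMetrics(
        peak_pa=peak,
        density_pa_per_pf=abs(peak) / geometry.capacitance_pf,
        capacitance_pf=geometry.capacitance_pf,
        ph=sweep.ph,
        holding_mv=sweep.holding_mv,
        desensitization=desens,
    )


def fit_desensitization(sweep: SweepRecording, direction: str = "inward") -> DesensFit:
    """Fit A exp(-t/tau) + C from the current peak to the pulse end.

    Currents are measured relative to the pre-pulse baseline; tau is
    returned in ms.  A non-decaying trace is flagged non-convergent
    rather than raising.
    """
    if sweep.clamp != "voltage":
        raise TypeError("desensitization requires a voltage-clamp sweep")
    if sweep.pulse_window is None:
        raise ValueError("sweep lacks pulse metadata")
    pre = sweep.time_s < sweep.pulse_window[0]
    baseline = float(np.mean(sweep.samples[pre])) if pre.any() else 0.0
    mask = sweep.window_mask(sweep.pulse_window)
    t = sweep.time_s[mask]
    y = sweep.samples[mask] - baseline
    k_peak = int(np.argmin(y) if direction == "inward" else np.argmax(y))
    t, y = t[k_peak:], y[k_peak:]
    if t.size < 3:
        return DesensFit(math.nan, math.nan, math.nan, math.nan, False, "peak too close to pulse end")
    model = ExponentialDecay().fit(t, y)
    return DesensFit(
        amplitude_pa=model.amplitude_,
        tau_ms=model.tau_ * 1000.0,
        steady_pa=model.offset_,
        rms_pa=model.rms_,
        converged=model.converged_,
        reason=model.reason_,
    )


def fit_hill_ph(points) -> HillFit:
    """Fit the Hill law to a (pH, response) table.

    ``points`` is anything with columns/fields ``ph`` and ``response``
    (a DataFrame, dict of arrays, or a 2-column array).
    """
    ph, resp = _two_columns(points, "ph", "response")
    model = HillCurve().fit(ph, resp)
    return HillFit(model.amax_, model.ph50_, model.hill_n_, model.rms_, model.converged_)


def fit_reversal(points) -> ReversalFit:
    """Quadratic interpolation of the reversal potential from an I-V table."""
    v, i = _two_columns(points, "v_mv", "i_pa")
    model = QuadraticIV().fit(v, i)
    return ReversalFit(model.coefficients_, model.vrev_, model.span_)


def nernst_potential(p: NernstParams) -> float:
    """Nernst equilibrium potential for Na+, in mV: (RT/F) ln([Na]o/[Na]i)."""
    if p.na_out_mm <= 0 or p.na_in_mm <= 0:
        raise ValueError("concentrations must be positive")
    return 1000.0 * GAS_CONSTANT * p.temperature_k / FARADAY * math.log(p.na_out_mm / p.na_in_mm)


def fit_tachyphylaxis(series) -> TachyFit:
    """Single-exponential fit of normalized peak run-down across pulses.

    ``series`` has columns ``time_s`` and ``amplitude`` (normalized to the
    first pulse).  Grossly increasing amplitude sequences and constant
    series are flagged non-convergent.
    """
    t, amp = _two_columns(series, "time_s", "amplitude")
    if t.size < 3:
        raise ValueError("need >= 3 pulses to fit tachyphylaxis")
    if not math.isclose(amp[0], 1.0, rel_tol=0.05):
        raise ValueError("amplitudes must be normalized to the first pulse")
    if amp[-1] > amp[0] + 1e-9 and np.all(np.diff(amp) >= -1e-12):
        return TachyFit(math.nan, math.nan, math.nan, math.nan, False,
                        "amplitudes increase: no run-down to fit")
    model = ExponentialDecay().fit(t, amp)
    if not model.converged_:
        return TachyFit(math.nan, math.nan, math.nan, model.rms_, False, model.reason_)
    return TachyFit(model.amplitude_, model.tau_, model.offset_, model.rms_, True)


def _two_columns(points, name_a: str, name_b: str):
    """Accept DataFrame/dict with named columns or a plain 2-column array."""
    if hasattr(points, "columns"):
        cols = list(points.columns)
        a = points[name_a] if name_a in cols else points[cols[0]]
        b = points[name_b] if name_b in cols else points[cols[1]]
        return np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if isinstance(points, dict):
        return np.asarray(points[name_a], dtype=float), np.asarray(points[name_b], dtype=float)
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a table with two columns")
    return arr[:, 0], arr[:, 1]
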