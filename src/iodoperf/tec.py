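"""Gamma-variate time-enhancement-curve (TEC) model and first-pass fitting.

The first pass of an iodine contrast bolus through a vascular bed is
modelled by the gamma-variate function

    I(t) = I0 + A * (t - t0)**alpha * exp(-(t - t0) / beta)    for t > t0
    I(t) = I0                                                  for t <= t0

where ``I(t)`` is the iodine density in mg/ml, ``A`` the amplitude
(mg/ml/s^alpha), ``t0`` the bolus-arrival time (s), ``alpha`` the
dimensionless shape, ``beta`` the time scale (s) and ``I0`` a constant
pre-contrast baseline (mg/ml).  The baseline term is an explicit extension
of the classical three-parameter bolus model: myocardial tissue carries a
small non-zero pre-contrast iodine-density reading, and peak enhancement is
defined relative to it (Imax - Imin).

Hemodynamic quantities have closed forms in these parameters:

* peak:       t_peak = t0 + alpha*beta,  I_peak = I0 + A*(alpha*beta)**alpha * e**-alpha
* max slope:  attained at t0 + beta*(alpha - sqrt(alpha)) for alpha > 1
* area:       lower incomplete gamma function of the baseline-free term

Recirculation (the delayed, attenuated second bolus transit) biases late
samples; :func:`fit_first_pass` implements a two-step procedure that first
locates a preliminary peak on all samples and then refits using only
samples no later than ``recirculation_cut`` seconds past that peak.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, special

from .exceptions import FitInputError

__all__ = [
    "GammaVariateParams",
    "TimeEnhancementCurve",
    "FitResult",
    "FitBounds",
    "MaxSlope",
    "gv_eval",
    "gv_derivative",
    "gv_peak",
    "gv_max_slope",
    "gv_integral",
    "truncated_volume",
    "fit_first_pass",
]


@dataclasses.dataclass(frozen=True)
class GammaVariateParams:
    """Parameters of a (baseline-shifted) gamma-variate bolus curve.

    amplitude
        ``A`` in mg/ml/s^alpha; scales the whole enhancement, > 0.
    t0
        Bolus-arrival time in seconds, >= 0.
    alpha
        Dimensionless shape parameter, > 0.  ``alpha <= 1`` gives a curve
        whose initial slope is not differentiable-bounded (see
        :func:`gv_max_slope`).
    beta
        Decay time scale in seconds, > 0.
    baseline
        Pre-contrast iodine density ``I0`` in mg/ml, >= 0.
    """

    amplitude: float
    t0: float
    alpha: float
    beta: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        for name in ("amplitude", "t0", "alpha", "beta", "baseline"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if not (self.amplitude > 0):
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if not (self.t0 >= 0):
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not (self.beta > 0):
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not (self.baseline >= 0):
            raise ValueError(f"baseline must be >= 0, got {self.baseline}")

    @property
    def t_peak(self) -> float:
        return self.t0 + self.alpha * self.beta


@dataclasses.dataclass(frozen=True)
class TimeEnhancementCurve:
    """One pixel's (or ROI's) iodine density versus acquisition time.

    ``times`` must be strictly increasing; ``densities`` has the same
    length.  Units are mg/ml on the density axis and seconds on the time
    axis; non-equidistant sampling is expected (frames rejected for motion
    leave gaps).
    """

    times: np.ndarray
    densities: np.ndarray
    units: str = "mg/ml"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.densities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "densities", d)
        if t.ndim != 1 or d.shape != t.shape:
            raise FitInputError("times and densities must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise FitInputError("times must be strictly increasing")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(d)):
            raise FitInputError("times and densities must be finite")

    def __len__(self) -> int:
        return int(self.times.size)


class MaxSlope(NamedTuple):
    """Location and value of the maximal upslope of a gamma-variate curve."""

    time: float
    slope: float
    analytic: bool  # False when alpha <= 1 (degenerate, grid-searched)


def _gv_term(amplitude: float, t0: float, alpha: float, beta: float, t: np.ndarray) -> np.ndarray:
    """Baseline-free gamma-variate term, vectorised and safe at t <= t0."""
    tau = np.asarray(t, dtype=float) - t0
    out = np.zeros_like(tau)
    m = tau > 0
    if np.any(m):
        tm = tau[m]
        out[m] = amplitude * np.exp(alpha * np.log(tm) - tm / beta)
    return out


def gv_eval(params: GammaVariateParams, t):
    """Evaluate the curve at time(s) ``t`` (seconds) -> iodine density in mg/ml."""
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    out = params.baseline + _gv_term(params.amplitude, params.t0, params.alpha, params.beta, np.atleast_1d(t))
    return float(out[0]) if scalar else out


def gv_derivative(params: GammaVariateParams, t):
    """Time derivative dI/dt in mg/ml/s (0 for t <= t0)."""
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    tau = np.atleast_1d(t) - params.t0
    out = np.zeros_like(tau)
    m = tau > 0
    if np.any(m):
        tm = tau[m]
        out[m] = (
            params.amplitude
            * np.exp((params.alpha - 1.0) * np.log(tm) - tm / params.beta)
            * (params.alpha - tm / params.beta)
        )
    return float(out[0]) if scalar else out


def gv_peak(params: GammaVariateParams) -> tuple[float, float]:
    """Peak location and density: (t0 + alpha*beta, I0 + A*(alpha*beta)^alpha * e^-alpha)."""
    ab = params.alpha * params.beta
    peak = params.baseline + params.amplitude * math.exp(
        params.alpha * math.log(ab) - params.alpha
    )
    return params.t0 + ab, peak


def gv_max_slope(params: GammaVariateParams, search_window: float | None = None) -> MaxSlope:
    """Maximal upslope of the curve (the maximal-slope perfusion estimate).

    For ``alpha > 1`` the maximum of dI/dt lies at ``t0 + beta*(alpha -
    sqrt(alpha))`` and is evaluated in closed form.  For ``alpha == 1`` the
    supremum ``A`` is attained at ``t0+``; for ``alpha < 1`` the rising
    slope is unbounded at ``t0+``.  Both degenerate cases are reported as
    the maximum of dI/dt over a dense grid on ``(t0, t0 + search_window]``
    with ``analytic=False`` so that downstream maps stay finite.
    """
    a, b, t0, A = params.alpha, params.beta, params.t0, params.amplitude
    if a > 1.0:
        tau = b * (a - math.sqrt(a))
        slope = A * math.exp((a - 1.0) * math.log(tau) - tau / b) * math.sqrt(a)
        return MaxSlope(t0 + tau, slope, True)
    if search_window is None:
        search_window = max(50.0, 10.0 * a * b)
    if a == 1.0:
        # limit of the derivative at t0+ is exactly A
        return MaxSlope(t0, A, False)
    grid = t0 + np.linspace(search_window * 1e-6, search_window, 200_001)
    dvals = gv_derivative(params, grid)
    i = int(np.argmax(dvals))
    return MaxSlope(float(grid[i]), float(dvals[i]), False)


def gv_integral(params: GammaVariateParams, t_start: float, t_end: float) -> float:
    """Area under the baseline-free term on [t_start, t_end], in mg/ml*s.

    Closed form via the regularised lower incomplete gamma function:
    ``A * beta**(alpha+1) * Gamma(alpha+1) * [P(alpha+1, x_end) - P(alpha+1, x_start)]``
    with ``x = max(0, (t - t0)/beta)``.  ``t_end`` may be ``inf``.
    """
    if not t_start < t_end:
        raise ValueError(f"t_start ({t_start}) must be < t_end ({t_end})")
    a1 = params.alpha + 1.0
    x0 = max(0.0, (t_start - params.t0) / params.beta)
    x1 = max(0.0, (t_end - params.t0) / params.beta) if np.isfinite(t_end) else np.inf
    scale = params.amplitude * params.beta ** a1 * special.gamma(a1)
    return float(scale * (special.gammainc(a1, x1) - special.gammainc(a1, x0)))


def truncated_volume(
    params: GammaVariateParams,
    window: float = 50.0,
    stop: float | None = 0.25,
) -> tuple[float, float]:
    """Iodine volume with the washout stop criterion.

    Integrates the baseline-free curve over ``[0, t_end]`` where ``t_end``
    is the earlier of ``window`` and the first post-peak time at which the
    *total* fitted density (baseline included) drops below ``stop`` mg/ml.
    Returns ``(volume, t_end)``.  ``stop=None`` (or 0) disables the
    criterion, giving the plain ``[0, window]`` integral.
    """
    t_end = float(window)
    if stop:
        t_pk, peak = gv_peak(params)
        if peak <= stop:
            t_end = min(t_end, t_pk)
        elif t_pk < window and gv_eval(params, window) < stop:
            t_end = float(optimize.brentq(
                lambda t: gv_eval(params, t) - stop, t_pk, window, xtol=1e-10
            ))
    if t_end <= 0.0:
        return 0.0, t_end
    return gv_integral(params, 0.0, t_end), t_end


@dataclasses.dataclass(frozen=True)
class FitBounds:
    """Box constraints for the fit; not physiological, exposed in config."""

    amplitude: tuple[float, float] = (1e-12, 100.0)
    t0: tuple[float, float] = (0.0, np.inf)  # upper replaced by max(times)
    alpha: tuple[float, float] = (0.1, 20.0)
    beta: tuple[float, float] = (0.05, 60.0)
    baseline: tuple[float, float] = (0.0, np.inf)  # upper replaced by max(densities)


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Outcome of the two-step first-pass fit for a single curve."""

    params: GammaVariateParams
    r_squared: float
    n_points_used: int
    preliminary_peak_time: float
    converged: bool
    used_fallback: bool = False  # step-2 exclusion left < 5 points; step-1 fit kept


def _robust_noise(d: np.ndarray) -> float:
    """Noise scale from successive differences (robust to the smooth trend)."""
    if d.size < 2:
        return 0.0
    return 1.4826 * float(np.median(np.abs(np.diff(d)))) / math.sqrt(2.0)


def _initial_guess(t: np.ndarray, d: np.ndarray, bounds: FitBounds) -> np.ndarray:
    """Deterministic, derivative-free starting point (A, t0, alpha, beta, I0)."""
    noise = max(_robust_noise(d), 1e-9)
    thresh = float(d.min()) + 3.0 * noise
    above = np.nonzero(d > thresh)[0]
    onset = int(above[0]) if above.size else d.size
    i0 = float(d[: max(onset, 1)].mean()) if onset >= 1 else float(d.min())
    i0 = max(i0, 0.0)
    rng = float(d.max()) - i0
    i_max = int(np.argmax(d))
    # t0: last sample still below 10 % of the observed range, before the peak
    below = np.nonzero((d <= i0 + 0.1 * rng) & (np.arange(d.size) < i_max))[0]
    t0 = float(t[below[-1]]) if below.size else float(t[0])

    # alpha, beta from log-linearisation of log(I - I0) = log A + alpha*log(tau) - tau/beta
    alpha, beta = 2.0, max((float(t[i_max]) - t0) / 2.0, 0.5)
    sel = (d - i0 > 0.05 * rng) & (t > t0 + 1e-9)
    if np.count_nonzero(sel) >= 3:
        tau = t[sel] - t0
        y = np.log(d[sel] - i0)
        X = np.column_stack([np.ones_like(tau), np.log(tau), -tau])
        try:
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            if coef[1] > 0 and coef[2] > 0:
                alpha, beta = float(coef[1]), float(1.0 / coef[2])
        except np.linalg.LinAlgError:
            pass
    alpha = float(np.clip(alpha, bounds.alpha[0] * 1.01, bounds.alpha[1] * 0.99))
    beta = float(np.clip(beta, bounds.beta[0] * 1.01, bounds.beta[1] * 0.99))
    # amplitude from the observed maximum at the model peak
    ab = alpha * beta
    amp = max(rng, noise) / math.exp(alpha * math.log(ab) - alpha)
    amp = float(np.clip(amp, bounds.amplitude[0] * 1.01, bounds.amplitude[1] * 0.99))
    return np.array([amp, t0, alpha, beta, i0])


def _model(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    amp, t0, alpha, beta, i0 = x
    return i0 + _gv_term(amp, t0, alpha, beta, t)


def _ls_fit(t: np.ndarray, d: np.ndarray, x0: np.ndarray, bounds: FitBounds, tol: float):
    lo = np.array([bounds.amplitude[0], bounds.t0[0], bounds.alpha[0], bounds.beta[0], bounds.baseline[0]])
    hi = np.array([
        bounds.amplitude[1],
        min(bounds.t0[1], float(t.max())),
        bounds.alpha[1],
        bounds.beta[1],
        min(bounds.baseline[1], float(d.max()) + 1e-12),
    ])
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
    res = optimize.least_squares(
        lambda x: _model(x, t) - d, x0, bounds=(lo, hi), method="trf",
        xtol=tol, ftol=tol, gtol=tol, max_nfev=2000,
    )
    # a fit pinned to a bound of A/alpha/beta (either end) or the t0 upper
    # bound did not find an interior optimum; t0 = 0 is a legitimate value
    x = res.x
    span = hi - lo
    at_bound = False
    for i in (0, 2, 3):
        at_bound |= (x[i] - lo[i]) < 1e-8 * span[i] or (hi[i] - x[i]) < 1e-8 * span[i]
    at_bound |= (hi[1] - x[1]) < 1e-8 * max(span[1], 1.0)
    return res, bool(res.success and not at_bound)


def _r_squared(d: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((d - pred) ** 2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def _failed(d: np.ndarray, n: int) -> FitResult:
    params = GammaVariateParams(1e-12, 0.0, 1.0, 1.0, max(float(np.mean(d)), 0.0))
    return FitResult(params, float("nan"), n, float("nan"), converged=False)


def fit_first_pass(
    curve: TimeEnhancementCurve,
    recirculation_cut: float | None = 12.0,
    *,
    bounds: FitBounds | None = None,
    tol: float = 1e-10,
    min_points: int = 5,
) -> FitResult:
    """Two-step gamma-variate fit of a first-pass contrast bolus.

    Step 1 fits all samples by bounded nonlinear least squares and yields a
    preliminary peak time.  Step 2 refits using only samples no later than
    ``recirculation_cut`` seconds past that peak, which removes the second
    (recirculated) bolus transit from the data.  Pass
    ``recirculation_cut=None`` for a plain single-step fit.

    Never raises for optimisation trouble: failures (including a flat,
    enhancement-free curve) come back with ``converged=False``.  If the
    step-2 exclusion would leave fewer than ``min_points`` samples the
    step-1 fit is returned with ``used_fallback=True``.
    """
    bounds = bounds or FitBounds()
    t, d = curve.times, curve.densities
    if len(curve) < min_points:
        raise FitInputError(f"need at least {min_points} samples, got {len(curve)}")
    if float(np.ptp(d)) < max(1e-8, 1e-9 * float(np.abs(d).max())):
        return _failed(d, len(curve))

    x0 = _initial_guess(t, d, bounds)
    try:
        res1, ok1 = _ls_fit(t, d, x0, bounds, tol)
    except Exception:
        return _failed(d, len(curve))
    prelim_peak = float(res1.x[1] + res1.x[2] * res1.x[3])

    def _result(res, ok, tt, dd, fallback=False) -> FitResult:
        amp, t0, alpha, beta, i0 = res.x
        try:
            params = GammaVariateParams(float(amp), float(t0), float(alpha), float(beta), float(i0))
        except ValueError:
            return _failed(dd, tt.size)
        return FitResult(
            params,
            _r_squared(dd, _model(res.x, tt)),
            int(tt.size),
            prelim_peak,
            converged=bool(ok),
            used_fallback=fallback,
        )

    if recirculation_cut is None:
        return _result(res1, ok1, t, d)

    keep = t <= prelim_peak + float(recirculation_cut)
    if int(keep.sum()) == len(curve):
        return _result(res1, ok1, t, d)
    if int(keep.sum()) < min_points:
        return _result(res1, ok1, t, d, fallback=True)
    t2, d2 = t[keep], d[keep]
    try:
        res2, ok2 = _ls_fit(t2, d2, res1.x, bounds, tol)
    except Exception:
        return _failed(d2, int(keep.sum()))
    return _result(res2, ok2, t2, d2)
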