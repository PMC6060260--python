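"""Kinetic summaries of normalized calcium transients.

From each F/F0 trace: peak amplitude and time to peak, initial slope
(least-squares over the first post-onset samples), the post-peak decay
time constant — fitted as either a single or double exponential, the
model chosen by small-sample-corrected AIC, with the fast phase reported
as the single tau or the faster of the two — and the area under the
curve for a fixed window after stimulation. Stimulus-response relations
across intensities are summarized with a four-parameter logistic
(sigmoid) or an ordinary least-squares line restricted to the linear
sub-range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .core import (
    DomainError,
    FitFailureError,
    ParameterError,
    ProtocolError,
    Trace,
)

__all__ = [
    "DecayFit",
    "KineticsSummary",
    "SigmoidFit",
    "LinearFit",
    "measure_peak",
    "measure_initial_slope",
    "fit_decay",
    "area_under_curve",
    "summarize_kinetics",
    "fit_sigmoid",
    "fit_linear_range",
]


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayFit:
    """Single- or double-exponential decay above the F/F0 = 1 baseline."""

    model: str                      # "single" | "double"
    amps: Tuple[float, ...]
    taus_s: Tuple[float, ...]
    fast_tau_s: float
    selection_score: float          # AICc difference (double - single)

    def __post_init__(self) -> None:
        if self.model not in ("single", "double"):
            raise ParameterError("model must be 'single' or 'double'")
        if len(self.taus_s) != (1 if self.model == "single" else 2):
            raise ParameterError("tau count does not match model")
        if any(tau <= 0 for tau in self.taus_s):
            raise ParameterError("time constants must be > 0")
        if abs(self.fast_tau_s - min(self.taus_s)) > 1e-12:
            raise ParameterError("fast_tau_s must be min(taus_s)")


@dataclass(frozen=True)
class KineticsSummary:
    """Peak, time-to-peak, initial slope, fast tau and AUC of one trace."""

    peak: float
    time_to_peak_s: float
    initial_slope_per_s: float
    fast_tau_s: Optional[float]
    auc: float


@dataclass(frozen=True)
class SigmoidFit:
    """Four-parameter logistic y = base + (top-base)/(1+exp((x50-x)/rate))."""

    base: float
    top: float
    x50: float
    rate: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and self.top < self.base:
            raise ParameterError("top must be >= base")
        if self.rate <= 0:
            raise ParameterError("rate must be > 0")

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.base + (self.top - self.base) / (
            1.0 + np.exp((self.x50 - x) / self.rate))


@dataclass(frozen=True)
class LinearFit:
    """OLS line over the linear sub-range, with its correlation."""

    slope: float
    intercept: float
    r: float

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.r <= 1 + 1e-12:
            raise ParameterError("r must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# Point measurements
# ---------------------------------------------------------------------------

def _require_normalized(trace: Trace) -> None:
    if trace.stage != "normalized":
        raise DomainError("kinetics expects a normalized (F/F0) trace")


def measure_peak(trace: Trace, stim_onset_s: float = 0.0
                 ) -> Tuple[float, float]:
    """Maximum post-onset F/F0 - 1 and its latency from onset (ties ->
    earliest sample)."""
    _require_normalized(trace)
    post = trace.times_s >= stim_onset_s
    if not post.any():
        raise ProtocolError("no samples after stimulus onset")
    values = trace.values[post]
    times = trace.times_s[post]
    idx = int(np.argmax(values))  # argmax returns the first maximum
    return float(values[idx] - 1.0), float(times[idx] - stim_onset_s)


def measure_initial_slope(trace: Trace, stim_onset_s: float = 0.0,
                          n_points: int = 3) -> float:
    """Least-squares slope of F/F0 vs time over the first ``n_points``
    post-onset samples."""
    _require_normalized(trace)
    if n_points < 2:
        raise ParameterError("n_points must be >= 2")
    post = np.flatnonzero(trace.times_s >= stim_onset_s)
    if post.size < n_points:
        raise ProtocolError(
            f"need {n_points} post-onset samples, have {post.size}")
    sel = post[:n_points]
    t = trace.times_s[sel]
    y = trace.values[sel]
    t_c = t - t.mean()
    return float(np.dot(t_c, y - y.mean()) / np.dot(t_c, t_c))


def area_under_curve(trace: Trace, stim_onset_s: float = 0.0,
                     duration_s: float = 2.0) -> float:
    """Trapezoidal integral of F/F0 - 1 over [onset, onset + duration].

    The window endpoints are linearly interpolated when they fall
    between samples.
    """
    _require_normalized(trace)
    t0, t1 = stim_onset_s, stim_onset_s + duration_s
    if trace.times_s[0] > t0 or trace.times_s[-1] < t1:
        raise ProtocolError("trace does not span the integration window")
    inside = (trace.times_s > t0) & (trace.times_s < t1)
    t = np.concatenate(([t0], trace.times_s[inside], [t1]))
    y = np.interp(t, trace.times_s, trace.values) - 1.0
    return float(np.trapezoid(y, t))


# ---------------------------------------------------------------------------
# Decay fitting with AICc model selection
# ---------------------------------------------------------------------------

def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-30 * n)  # floor keeps noiseless fits finite
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = np.inf
    return aic


def _fit_single_decay(t, y, tau_grid):
    best, best_rss = None, np.inf

    def f(t, a, tau):
        return 1.0 + a * np.exp(-t / tau)

    amp0 = max(y[0] - 1.0, 1e-6)
    for tau in tau_grid:
        try:
            popt, _ = curve_fit(f, t, y, p0=[amp0, tau],
                                bounds=([0, 1e-9], [np.inf, np.inf]),
                                maxfev=10000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((f(t, *popt) - y) ** 2))
        if rss < best_rss:
            best, best_rss = popt, rss
    return best, best_rss


def _fit_double_decay(t, y, tau_grid):
    best, best_rss = None, np.inf

    def f(t, a1, tau1, a2, tau2):
        return 1.0 + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)

    amp0 = max((y[0] - 1.0) / 2.0, 1e-6)
    for tau1 in tau_grid:
        tau2 = tau1 * 10.0
        try:
            popt, _ = curve_fit(f, t, y, p0=[amp0, tau1, amp0, tau2],
                                bounds=([0, 1e-9, 0, 1e-9],
                                        [np.inf] * 4),
                                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((f(t, *popt) - y) ** 2))
        if rss < best_rss:
            best, best_rss = popt, rss
    return best, best_rss


def fit_decay(trace: Trace, peak_time_s: float,
              n_starts: int = 5) -> DecayFit:
    """Fit the post-peak decay as 1 + sum_i a_i exp(-(t - t_peak)/tau_i).

    Both a one- and a two-component model are fitted (multi-start over
    log-spaced initial time constants); corrected AIC selects between
    them, with the single model winning ties. ``fast_tau_s`` is the
    single tau or the faster of the two.
    """
    _require_normalized(trace)
    post = trace.times_s >= peak_time_s
    if post.sum() < 6:
        raise ProtocolError("need >= 6 samples after the peak")
    t = trace.times_s[post] - peak_time_s
    y = trace.values[post]
    n = t.size
    span = max(t[-1], 1e-6)
    tau_grid = np.geomspace(span * 1e-2, span * 2, max(n_starts, 2))

    p_single, rss_single = _fit_single_decay(t, y, tau_grid)
    p_double, rss_double = _fit_double_decay(t, y, tau_grid)
    if p_single is None and p_double is None:
        raise FitFailureError("decay fit did not converge",
                              best_residual=min(rss_single, rss_double))

    aicc_single = _aicc(rss_single, n, 2) if p_single is not None else np.inf
    aicc_double = _aicc(rss_double, n, 4) if p_double is not None else np.inf
    score = aicc_double - aicc_single

    a1, tau1, a2, tau2 = p_double if p_double is not None else (0, 1, 0, 1)
    total = a1 + a2
    dt_med = float(np.median(np.diff(t)))
    # a component is not a decay phase if its amplitude vanishes or its
    # time constant is below the sampling interval (a one-sample spike)
    negligible = total > 0 and (min(a1, a2) < 0.05 * total
                                or min(tau1, tau2) < dt_med)
    # parsimony margin: models within 2 AICc units are equivalent, so the
    # single exponential wins unless the double is clearly better
    if aicc_single <= aicc_double + 2.0 or negligible:
        if p_single is not None and (aicc_single <= aicc_double
                                     or p_double is None):
            a, tau = p_single
        else:
            a, tau = (a1, tau1) if a1 >= a2 else (a2, tau2)
        return DecayFit(model="single", amps=(float(a),),
                        taus_s=(float(tau),), fast_tau_s=float(tau),
                        selection_score=float(score))
    if tau1 > tau2:
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    return DecayFit(model="double", amps=(float(a1), float(a2)),
                    taus_s=(float(tau1), float(tau2)),
                    fast_tau_s=float(tau1), selection_score=float(score))


def summarize_kinetics(trace: Trace, stim_onset_s: float = 0.0,
                       auc_duration_s: float = 2.0,
                       slope_points: int = 3) -> KineticsSummary:
    """All standard kinetic measurements of one normalized trace.

    The decay fit is skipped (``fast_tau_s = None``) when too few
    post-peak samples exist or the fit fails.
    """
    peak, ttp = measure_peak(trace, stim_onset_s)
    slope = measure_initial_slope(trace, stim_onset_s, slope_points)
    auc = area_under_curve(trace, stim_onset_s, auc_duration_s)
    fast_tau: Optional[float] = None
    try:
        fast_tau = fit_decay(trace, stim_onset_s + ttp).fast_tau_s
    except (ProtocolError, FitFailureError):
        pass
    return KineticsSummary(peak=peak, time_to_peak_s=ttp,
                           initial_slope_per_s=slope,
                           fast_tau_s=fast_tau, auc=auc)


# ---------------------------------------------------------------------------
# Stimulus-response curve fits
# ---------------------------------------------------------------------------

def fit_sigmoid(x, y, n_starts: int = 7) -> SigmoidFit:
    """Least-squares 4-parameter logistic with multi-start on x50."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ParameterError("need >= 5 paired points")
    if np.ptp(x) == 0:
        raise FitFailureError("degenerate abscissa spread")
    if np.ptp(y) < 1e-12 * max(1.0, np.abs(y).max()):
        # flat response: no sigmoid information
        return SigmoidFit(base=float(y.mean()), top=float(y.mean()),
                          x50=float(x.mean()), rate=float(np.ptp(x)) or 1.0,
                          degenerate=True)

    def f(x, base, top, x50, rate):
        return base + (top - base) / (1.0 + np.exp((x50 - x) / rate))

    best, best_rss = None, np.inf
    rate0 = np.ptp(x) / 10.0
    for x50 in np.linspace(x.min(), x.max(), n_starts):
        p0 = [float(y.min()), float(y.max()), float(x50), rate0]
        try:
            popt, _ = curve_fit(
                f, x, y, p0=p0,
                bounds=([-np.inf, -np.inf, -np.inf, 1e-12],
                        [np.inf, np.inf, np.inf, np.inf]),
                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((f(x, *popt) - y) ** 2))
        if rss < best_rss:
            best, best_rss = popt, rss
    if best is None:
        raise FitFailureError("sigmoid fit did not converge")
    base, top, x50, rate = best
    if top < base:
        raise FitFailureError(
            "sigmoid fit converged to a decreasing relationship")
    return SigmoidFit(base=float(base), top=float(top),
                      x50=float(x50), rate=float(rate))


def fit_linear_range(x, y, x_max: float) -> LinearFit:
    """OLS line restricted to points with x < x_max."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = x < x_max
    if keep.sum() < 2:
        raise ParameterError("need >= 2 points below the cutoff")
    res = stats.linregress(x[keep], y[keep])
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r=float(res.rvalue))
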