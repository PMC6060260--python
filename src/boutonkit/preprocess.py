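"""Photobleach compensation and F/F0 normalization.

Photobleaching is estimated from no-stimulus control acquisitions: the
control trace is fitted with a double exponential

    F(t) = F0 * (a1 * exp(-t/tau1) + a2 * exp(-t/tau2) + c)

normalized so that B(0) = a1 + a2 + c = 1, and stimulated traces are
*divided* by B(t). Division (rather than subtraction) is used because
bleaching scales the emitted fluorescence multiplicatively; correcting a
pure-bleach trace this way yields a constant.

F/F0 normalization divides by the mean of all pre-stimulus samples and
re-references time so the last pre-stimulus sample sits at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.optimize import curve_fit

from .core import (
    DomainError,
    FitFailureError,
    ParameterError,
    ProtocolError,
    ShapeError,
    Trace,
)

__all__ = [
    "BleachModel",
    "fit_bleach_model",
    "correct_bleach",
    "subtract_background",
    "compute_f_over_f0",
]


@dataclass(frozen=True)
class BleachModel:
    """Normalized double-exponential bleach curve B(t), with B(0) = 1.

    ``tau1_s <= tau2_s`` by convention (the fitter swaps if needed);
    ``single`` records a fallback to a one-component fit.
    """

    a1: float
    tau1_s: float
    a2: float
    tau2_s: float
    c: float
    single: bool = False

    def __post_init__(self) -> None:
        if self.tau1_s <= 0 or self.tau2_s <= 0:
            raise ParameterError("bleach time constants must be > 0")
        if self.tau1_s > self.tau2_s:
            raise ParameterError("convention requires tau1_s <= tau2_s")
        if min(self.a1, self.a2, self.c) < -1e-9:
            raise ParameterError("amplitude fractions must be >= 0")
        if abs(self.a1 + self.a2 + self.c - 1.0) > 1e-6:
            raise ParameterError("a1 + a2 + c must equal 1 (B(0) = 1)")

    @classmethod
    def identity(cls) -> "BleachModel":
        """No-bleach model: B(t) = 1."""
        return cls(a1=0.0, tau1_s=1.0, a2=0.0, tau2_s=1.0, c=1.0)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.a1 * np.exp(-t / self.tau1_s)
                + self.a2 * np.exp(-t / self.tau2_s) + self.c)

    def to_dict(self) -> dict:
        return {"a1": self.a1, "tau1_s": self.tau1_s, "a2": self.a2,
                "tau2_s": self.tau2_s, "c": self.c, "single": self.single}

    @classmethod
    def from_dict(cls, d: dict) -> "BleachModel":
        return cls(**d)


def _double_exp(t, p1, tau1, p2, tau2, p3):
    return p1 * np.exp(-t / tau1) + p2 * np.exp(-t / tau2) + p3


def _single_exp(t, p1, tau1, p3):
    return p1 * np.exp(-t / tau1) + p3


def fit_bleach_model(control: Trace, n_starts: int = 5) -> BleachModel:
    """Fit a normalized double-exponential bleach model to a control trace.

    Multi-start nonlinear least squares over ``n_starts`` log-spaced
    time-constant initializations (tau pairs one decade apart). If no
    double-exponential start converges, falls back to a single
    exponential and flags the result with ``single=True``.

    Raises
    ------
    DomainError
        If the control is not a raw trace of positive values.
    FitFailureError
        If neither model converges; carries the best residual seen.
    """
    if control.stage != "raw":
        raise DomainError("bleach control must be a raw trace")
    if len(control) < 10:
        raise DomainError("bleach fit needs at least 10 samples")
    if np.any(control.values <= 0):
        raise DomainError("bleach control must be strictly positive")

    t = control.times_s - control.times_s[0]
    y = control.values
    span = max(t[-1], 10 * np.median(np.diff(t)))
    scale = float(np.mean(y))
    tau_grid = np.geomspace(max(span * 1e-3, 1e-6), 10 * span,
                            max(n_starts, 2))

    best = None
    best_res = np.inf
    lower = [0.0, 1e-12, 0.0, 1e-12, 0.0]
    upper = [10 * scale, np.inf, 10 * scale, np.inf, 10 * scale]
    for tau1 in tau_grid:
        tau2 = min(tau1 * 10, 10 * span)
        p0 = [0.5 * (y[0] - y[-1]) + 1e-9 * scale, tau1,
              0.5 * (y[0] - y[-1]) + 1e-9 * scale, tau2, y[-1]]
        p0 = [max(v, lb) for v, lb in zip(p0, lower)]
        try:
            popt, _ = curve_fit(_double_exp, t, y, p0=p0,
                                bounds=(lower, upper), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        res = float(np.sum((_double_exp(t, *popt) - y) ** 2))
        if res < best_res:
            best_res, best = res, popt

    if best is not None:
        p1, tau1, p2, tau2, p3 = best
        if tau1 > tau2:
            p1, tau1, p2, tau2 = p2, tau2, p1, tau1
        f0 = p1 + p2 + p3
        if f0 > 0:
            return BleachModel(a1=p1 / f0, tau1_s=float(tau1),
                               a2=p2 / f0, tau2_s=float(tau2),
                               c=p3 / f0, single=False)

    # single-exponential fallback
    for tau1 in tau_grid:
        p0 = [max(y[0] - y[-1], 1e-9 * scale), tau1, max(y[-1], 1e-9 * scale)]
        try:
            popt, _ = curve_fit(_single_exp, t, y, p0=p0,
                                bounds=([0.0, 1e-12, 0.0],
                                        [10 * scale, np.inf, 10 * scale]),
                                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        res = float(np.sum((_single_exp(t, *popt) - y) ** 2))
        if res < best_res:
            p1, tau1, p3 = popt
            f0 = p1 + p3
            if f0 > 0:
                return BleachModel(a1=p1 / f0, tau1_s=float(tau1),
                                   a2=0.0, tau2_s=float(tau1),
                                   c=p3 / f0, single=True)

    raise FitFailureError("bleach model did not converge", best_residual=best_res)


def correct_bleach(trace: Trace, model: BleachModel) -> Trace:
    """Divide a raw trace by the bleach curve evaluated at its times."""
    if trace.stage != "raw":
        raise DomainError("correct_bleach expects a raw trace")
    t = trace.times_s - trace.times_s[0]
    b = model(t)
    if np.any(b <= 0):
        raise DomainError("bleach model is non-positive at some sample times")
    return trace.with_values(trace.values / b, stage="bleach_corrected")


def subtract_background(trace: Trace,
                        background: Union[Trace, float]) -> Trace:
    """Pointwise background subtraction; negative results are retained."""
    if isinstance(background, Trace):
        if len(background) != len(trace):
            raise ShapeError("background trace length mismatch")
        bg = background.values
    else:
        bg = float(background)
    return trace.with_values(trace.values - bg)


def compute_f_over_f0(trace: Trace, stim_onset_s: float) -> Trace:
    """Normalize a trace to its pre-stimulus baseline.

    F0 is the mean of all samples strictly before ``stim_onset_s``;
    values become F/F0 and times are re-referenced so the last
    pre-stimulus sample is t = 0 (responses plot relative to stimulation
    onset).
    """
    if trace.stage not in ("raw", "bleach_corrected"):
        raise DomainError("F/F0 expects a raw or bleach-corrected trace")
    pre = trace.times_s < stim_onset_s
    if pre.sum() < 2:
        raise ProtocolError("need >= 2 samples before stimulus onset")
    f0 = float(np.mean(trace.values[pre]))
    if f0 <= 0:
        raise DomainError(f"non-positive baseline F0 = {f0}")
    t_zero = trace.times_s[pre][-1]
    return Trace(times_s=trace.times_s - t_zero,
                 values=trace.values / f0,
                 stage="normalized", f0=f0, roi_id=trace.roi_id,
                 mask=trace.mask)
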