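"""Shared data model for two-channel presynaptic calcium imaging.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``, row-major, with pixel
  centers at integer coordinates;
* within one channel, sample ``i`` sits at ``i * frame_interval_s`` from
  that channel's first frame (the half-frame offset between interleaved
  channels is ignored — it is far below every fitted time constant);
* fluorescence is non-negative on read; traces carry a ``stage`` tag so
  each processing step can assert what it receives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "BoutonkitError",
    "MalformedInputError",
    "MetadataError",
    "ParameterError",
    "ShapeError",
    "DomainError",
    "ProtocolError",
    "FitFailureError",
    "DegenerateInputError",
    "EmptySelectionError",
    "StimulusProtocol",
    "TwoChannelStack",
    "Trace",
    "Roi",
    "TRACE_STAGES",
]


# ---------------------------------------------------------------------------
# Errors (one class per failure mode; the CLI maps these to exit codes)
# ---------------------------------------------------------------------------

class BoutonkitError(Exception):
    """Base class for all package errors."""


class MalformedInputError(BoutonkitError):
    """Input file or array violates its format contract (e.g. odd page count)."""


class MetadataError(BoutonkitError):
    """Required acquisition metadata is missing or invalid."""


class ParameterError(BoutonkitError):
    """A parameter is outside its valid range."""


class ShapeError(BoutonkitError):
    """Array/trace geometries are incompatible."""


class DomainError(BoutonkitError):
    """A value is outside the mathematical domain of an operation (e.g. F0 <= 0)."""


class ProtocolError(BoutonkitError):
    """The stimulus protocol and the trace do not fit together."""


class FitFailureError(BoutonkitError):
    """Nonlinear fit failed to converge; carries the best residual seen."""

    def __init__(self, message: str, best_residual: Optional[float] = None):
        super().__init__(message)
        self.best_residual = best_residual


class DegenerateInputError(BoutonkitError):
    """Input has no usable variation (e.g. zero variance for a correlation)."""


class EmptySelectionError(BoutonkitError):
    """A selection/mask selected nothing."""


# ---------------------------------------------------------------------------
# Stimulus protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """Electrical stimulation train delivered during an acquisition.

    Parameters
    ----------
    onset_time_s:
        Time of the first stimulus, seconds from the first frame.
    n_stimuli:
        Number of stimuli in the train.
    frequency_hz:
        Train frequency; must be positive whenever more than one
        stimulus is delivered.
    intensity_v:
        Nominal stimulus intensity label in volts (metadata only).
    """

    onset_time_s: float
    n_stimuli: int
    frequency_hz: float = 20.0
    intensity_v: float = 20.0

    def __post_init__(self) -> None:
        if self.onset_time_s < 0:
            raise ParameterError("onset_time_s must be >= 0")
        if self.n_stimuli < 0:
            raise ParameterError("n_stimuli must be >= 0")
        if self.n_stimuli > 1 and self.frequency_hz <= 0:
            raise ParameterError("frequency_hz must be > 0 for a train")

    def stimulus_times_s(self) -> np.ndarray:
        """Times of the individual stimuli, seconds from the first frame."""
        if self.n_stimuli == 0:
            return np.empty(0)
        if self.n_stimuli == 1:
            return np.array([self.onset_time_s])
        period = 1.0 / self.frequency_hz
        return self.onset_time_s + period * np.arange(self.n_stimuli)

    def end_time_s(self) -> float:
        times = self.stimulus_times_s()
        return float(times[-1]) if times.size else self.onset_time_s


# ---------------------------------------------------------------------------
# Two-channel stack
# ---------------------------------------------------------------------------

@dataclass
class TwoChannelStack:
    """Time-ordered green and red frame arrays plus acquisition metadata.

    ``green`` and ``red`` are ``(T, H, W)`` arrays in arbitrary
    fluorescence units, already separated from the interleaved
    acquisition.
    """

    green: np.ndarray
    red: np.ndarray
    frame_interval_s: float
    stim: Optional[StimulusProtocol] = None
    pixel_origin: str = "upper-left-0-based"

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.green.ndim != 3 or self.red.ndim != 3:
            raise ShapeError("channel arrays must be (T, H, W)")
        if self.green.shape != self.red.shape:
            raise ShapeError(
                f"green {self.green.shape} and red {self.red.shape} differ"
            )
        if self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be > 0")
        if np.any(self.green < 0) or np.any(self.red < 0):
            raise DomainError("fluorescence intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.green.shape[1:]

    def times_s(self) -> np.ndarray:
        """Per-channel sample times (seconds from that channel's first frame)."""
        return np.arange(self.n_frames) * self.frame_interval_s


# ---------------------------------------------------------------------------
# Trace
# ---------------------------------------------------------------------------

TRACE_STAGES = ("raw", "bleach_corrected", "normalized", "ratio")


@dataclass
class Trace:
    """One fluorescence time series with its time base and provenance.

    ``stage`` records how far through the pipeline the values are:
    ``raw`` counts, ``bleach_corrected`` counts, ``normalized`` (F/F0,
    with ``f0`` holding the baseline) or ``ratio`` (green/red).
    """

    times_s: np.ndarray
    values: np.ndarray
    stage: str = "raw"
    f0: Optional[float] = None
    roi_id: Optional[str] = None
    mask: Optional[np.ndarray] = None  # True where the sample is invalid

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise ShapeError("times_s and values must be equal-length 1-D arrays")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ShapeError("times_s must be strictly increasing")
        if self.stage not in TRACE_STAGES:
            raise ParameterError(f"unknown stage {self.stage!r}")
        if self.stage == "normalized":
            if self.f0 is None or self.f0 <= 0:
                raise DomainError("normalized trace requires f0 > 0")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ShapeError("mask must match values")

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, stage: Optional[str] = None,
                    **kw) -> "Trace":
        """Copy of this trace with new values (and optionally a new stage)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       stage=stage if stage is not None else self.stage, **kw)


def common_time_base(traces: Sequence[Trace]) -> np.ndarray:
    """Return the shared time axis of ``traces`` or raise :class:`ShapeError`."""
    if not traces:
        raise EmptySelectionError("no traces given")
    t0 = traces[0].times_s
    for tr in traces[1:]:
        if tr.times_s.shape != t0.shape or not np.allclose(tr.times_s, t0,
                                                           rtol=0, atol=1e-12):
            raise ShapeError("traces do not share a common time base")
    return t0


# ---------------------------------------------------------------------------
# ROI
# ---------------------------------------------------------------------------

ROI_KINDS = ("punctum", "fixed3x3", "region", "background")


@dataclass
class Roi:
    """A labeled pixel set with a designated center.

    ``pixels`` is a frozenset of 0-based ``(row, col)`` tuples; ``center``
    must be a member. ``fixed3x3`` ROIs fit inside the 3x3 window around
    the center (border-cropped ROIs may hold fewer than 9 pixels).
    """

    id: str
    pixels: frozenset
    center: Tuple[int, int]
    kind: str = "region"

    def __post_init__(self) -> None:
        self.pixels = frozenset((int(r), int(c)) for r, c in self.pixels)
        self.center = (int(self.center[0]), int(self.center[1]))
        if not self.pixels:
            raise ParameterError("ROI pixel set must be non-empty")
        if self.center not in self.pixels:
            raise ParameterError("ROI center must be one of its pixels")
        if self.kind not in ROI_KINDS:
            raise ParameterError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "fixed3x3":
            if len(self.pixels) > 9:
                raise ParameterError("fixed3x3 ROI has more than 9 pixels")
            cr, cc = self.center
            for r, c in self.pixels:
                if abs(r - cr) > 1 or abs(c - cc) > 1:
                    raise ParameterError("fixed3x3 pixels exceed 3x3 window")

    def __len__(self) -> int:
        return len(self.pixels)

    def rows_cols(self) -> Tuple[np.ndarray, np.ndarray]:
        """Pixel coordinates as two arrays, sorted row-major (deterministic)."""
        px = sorted(self.pixels)
        rows = np.array([p[0] for p in px], dtype=int)
        cols = np.array([p[1] for p in px], dtype=int)
        return rows, cols
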