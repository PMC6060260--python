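"""Line-profile colocalization.

Colocalization of two fluorophores is quantified by the Pearson
correlation of their intensities sampled along a line drawn through the
stained section, with a two-sided p-value from the t-distribution with
n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .core import DegenerateInputError, ParameterError, ShapeError

__all__ = ["ProfilePair", "pearson_profile"]


@dataclass
class ProfilePair:
    """Paired intensity samples along one line."""

    a: np.ndarray
    b: np.ndarray
    distance: Optional[np.ndarray] = None  # position along the line

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ShapeError("profiles must be equal-length 1-D arrays")
        if self.a.size < 3:
            raise ParameterError("need at least 3 samples")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ParameterError("profiles must be finite")
        if self.distance is not None:
            self.distance = np.asarray(self.distance, dtype=float)
            if self.distance.shape != self.a.shape:
                raise ShapeError("distance must match the profiles")


def pearson_profile(pair: ProfilePair) -> Tuple[float, float]:
    """Sample Pearson r of the two profiles and its two-sided p-value."""
    if pair.a.std() == 0 or pair.b.std() == 0:
        raise DegenerateInputError("zero variance in a profile")
    res = stats.pearsonr(pair.a, pair.b)
    return float(res.statistic), float(res.pvalue)
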