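"""Fixed-bin-count gray-level discretization shared by the histogram and
texture features."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretizationSpec:
    """Fixed-bin-count discretization of (windowed) intensities.

    Each region's intensity range is split into ``bins`` equal-width bins;
    gray levels are 1-based (IBSI convention).
    """

    bins: int = 32

    def __post_init__(self) -> None:
        if self.bins < 8:
            raise ValueError("need at least 8 gray-level bins")


def discretize(values: np.ndarray, spec: DiscretizationSpec) -> np.ndarray:
    """Map intensities to gray levels 1..bins over the value range."""
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=np.int64)
    g = np.floor((values - lo) / (hi - lo) * spec.bins).astype(np.int64) + 1
    return np.clip(g, 1, spec.bins)
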