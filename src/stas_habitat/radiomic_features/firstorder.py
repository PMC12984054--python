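"""First-order (intensity histogram) features of a masked voxel list."""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizationSpec, discretize

FIRSTORDER_FEATURES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(
    values: np.ndarray,
    voxel_volume_mm3: float = 1.0,
    spec: DiscretizationSpec | None = None,
) -> dict[str, float]:
    """The 18 first-order statistics of a region's intensity values.

    Entropy and uniformity are computed on the fixed-bin-count discretized
    histogram; kurtosis is the non-excess (Pearson) form.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty region")
    spec = spec or DiscretizationSpec()
    n = x.size
    mean = x.mean()
    centred = x - mean
    m2 = float((centred**2).mean())
    std = np.sqrt(m2)
    skew = float((centred**3).mean() / std**3) if std > 0 else 0.0
    kurt = float((centred**4).mean() / m2**2) if m2 > 0 else 0.0

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    band = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(band - band.mean()).mean()) if band.size else 0.0

    g = discretize(x, spec)
    p = np.bincount(g)[1:] / n
    p_nz = p[p > 0]
    entropy = float(-(p_nz * np.log2(p_nz)).sum())
    uniformity = float((p**2).sum())

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume_mm3 * energy,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(centred).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": m2,
        "Uniformity": uniformity,
    }
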