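"""Habitat subregion clustering from voxel-level local statistics.

Each tumor voxel is summarized by 19 first-order statistics of the 5×5×5
window centred on it (windows are clipped at the volume border, never padded).
Voxels of one tumor are then clustered with K-means; the cluster count k is
chosen cohort-wide by maximizing the per-sample mean Calinski–Harabasz (CH)
index over k = 2..8.  Cluster labels are made comparable across patients by
relabeling in increasing order of cluster mean windowed intensity (label 1 =
darkest habitat).

The feature map expects a windowed (lung-window normalized, [0, 1]) CT; the
entropy/uniformity statistics use 32 fixed bins on [0, 1] so they are stable
across windows and patients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .ct_preprocess import CTVolume, RegionMask

log = logging.getLogger(__name__)

N_ENTROPY_BINS = 32

FEATURE_NAMES = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "range",
    "variance",
    "std",
    "skewness",
    "kurtosis",
    "energy",
    "rms",
    "entropy",
    "uniformity",
    "mad",
    "rmad",
    "p10",
    "p25",
    "p75",
    "p90",
)


@dataclass
class VoxelFeatureMap:
    """Per-tumor-voxel matrix of the 19 local statistics.

    ``features`` has one row per tumor voxel in the order of ``voxel_index``
    (an (n, 3) array of voxel coordinates); ``intensity`` keeps the windowed
    CT value at each voxel for the cross-patient relabeling rule.
    """

    features: np.ndarray
    voxel_index: np.ndarray
    intensity: np.ndarray
    window_size: int = 5
    shape: tuple[int, int, int] = (0, 0, 0)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.features.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features per voxel")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("voxel features must be finite")


@dataclass
class HabitatMap:
    """Tumor partition into k habitat subregions (labels 1..k on the tumor)."""

    labels: RegionMask
    k: int
    fractions: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(self.fractions.sum()) - 1.0) > 1e-9:
            raise ValueError("habitat fractions must sum to 1")


@dataclass
class KSelectionResult:
    """Cohort-wide cluster-count selection by mean CH index."""

    k_grid: tuple[int, ...]
    ch_scores: dict[int, float]
    k_star: int
    per_sample: dict[int, list[float]] = field(default_factory=dict)


def local_feature_map(ct: CTVolume, tumor: RegionMask, window: int = 5) -> VoxelFeatureMap:
    """Compute the 19 local statistics for every tumor voxel.

    The window is ``window``³ voxels centred on the voxel and clipped at the
    volume border.  Statistics: mean, median, min, max, range, variance,
    standard deviation, skewness, kurtosis, energy (Σx²), root-mean-square,
    entropy (−Σp·log₂p over 32 fixed bins on [0, 1]), uniformity (Σp²),
    mean absolute deviation, robust MAD (values within [P10, P90]), and
    percentiles 10/25/75/90.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer ≥ 3")
    if any(window > n for n in ct.shape):
        raise ValueError(f"window {window} exceeds volume shape {ct.shape}")
    if not tumor.same_grid_as(ct):
        raise ValueError("tumor mask must be aligned with the CT")
    coords = np.argwhere(tumor.binary())
    if coords.shape[0] == 0:
        raise ValueError("empty tumor mask")

    half = window // 2
    # statistics are taken over window ∩ tumor: habitat features describe
    # intratumoral texture, so extratumoral voxels never enter a window
    masked = np.where(tumor.binary(), ct.values.astype(np.float64), np.nan)
    padded = np.pad(masked, half, constant_values=np.nan)
    win = np.lib.stride_tricks.sliding_window_view(padded, (window, window, window))
    # rows: (n_voxels, window³); NaN marks out-of-volume cells of border windows
    rows = win[coords[:, 0], coords[:, 1], coords[:, 2]].reshape(coords.shape[0], -1)

    valid = ~np.isnan(rows)
    n = valid.sum(axis=1).astype(np.float64)

    # order statistics via one sort (NaNs sort to the end of each row)
    srt = np.sort(rows, axis=1)
    nn = n.astype(np.int64)
    mn = srt[:, 0]
    mx = np.take_along_axis(srt, (nn - 1)[:, None], axis=1).ravel()

    def pct(q: float) -> np.ndarray:
        pos = (q / 100.0) * (nn - 1)
        lo_i = np.floor(pos).astype(np.int64)
        hi_i = np.ceil(pos).astype(np.int64)
        frac = (pos - lo_i)[:, None]
        lo_v = np.take_along_axis(srt, lo_i[:, None], axis=1)
        hi_v = np.take_along_axis(srt, hi_i[:, None], axis=1)
        return (lo_v * (1.0 - frac) + hi_v * frac).ravel()

    med, p10, p25, p75, p90 = pct(50), pct(10), pct(25), pct(75), pct(90)
    mean = np.where(valid, rows, 0.0).sum(axis=1) / n

    centred = np.where(valid, rows - mean[:, None], 0.0)
    m2 = (centred**2).sum(axis=1) / n
    m3 = (centred**3).sum(axis=1) / n
    m4 = (centred**4).sum(axis=1) / n
    std = np.sqrt(m2)
    denom = np.where(m2 > 0, m2, 1.0)
    skew = np.where(m2 > 0, m3 / denom**1.5, 0.0)
    kurt = np.where(m2 > 0, m4 / denom**2.0, 0.0)

    sq = np.where(valid, rows**2, 0.0)
    energy = sq.sum(axis=1)
    rms = np.sqrt(energy / n)
    mad = np.abs(centred).sum(axis=1) / n

    # robust MAD: mean |x − mean(x in [P10, P90])| over that trimmed set
    in_band = valid & (rows >= p10[:, None]) & (rows <= p90[:, None])
    n_band = np.maximum(in_band.sum(axis=1), 1)
    band_vals = np.where(in_band, rows, 0.0)
    band_mean = band_vals.sum(axis=1) / n_band
    rmad = np.where(in_band, np.abs(rows - band_mean[:, None]), 0.0).sum(axis=1) / n_band

    # histogram statistics on 32 fixed bins over [0, 1]
    filled = np.where(valid, rows, 0.0)
    idx = np.clip((filled * N_ENTROPY_BINS).astype(np.int64), 0, N_ENTROPY_BINS - 1)
    flat = idx + np.arange(rows.shape[0])[:, None] * N_ENTROPY_BINS
    counts = np.bincount(
        flat[valid], minlength=rows.shape[0] * N_ENTROPY_BINS
    ).reshape(rows.shape[0], N_ENTROPY_BINS)
    p = counts / n[:, None]
    logp = np.log2(p, out=np.zeros_like(p), where=p > 0)
    entropy = -(p * logp).sum(axis=1)
    uniformity = (p**2).sum(axis=1)

    features = np.column_stack(
        [mean, med, mn, mx, mx - mn, m2, std, skew, kurt, energy, rms,
         entropy, uniformity, mad, rmad, p10, p25, p75, p90]
    )
    return VoxelFeatureMap(
        features=features,
        voxel_index=coords,
        intensity=ct.values[coords[:, 0], coords[:, 1], coords[:, 2]].astype(np.float64),
        window_size=window,
        shape=ct.shape,
        spacing_mm=ct.spacing_mm,
        origin=ct.origin,
    )


def ch_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Calinski–Harabasz index: [B/(k−1)] / [W/(n−k)].

    B = Σ_j n_j‖c_j − c‖², W = Σ_j Σ_{i∈j} ‖x_i − c_j‖².  Returns +inf (with a
    warning) when W = 0, i.e. every cluster is a single point cloud of zero
    spread.
    """
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = uniq.size, points.shape[0]
    if k < 2:
        raise ValueError("CH index requires at least 2 clusters")
    if n != labels.size:
        raise ValueError("points and labels disagree in length")
    grand = points.mean(axis=0)
    B = 0.0
    W = 0.0
    for u in uniq:
        grp = points[labels == u]
        c = grp.mean(axis=0)
        B += grp.shape[0] * float(np.sum((c - grand) ** 2))
        W += float(np.sum((grp - c) ** 2))
    if W == 0.0:
        warnings.warn("zero within-cluster scatter; CH index is +inf")
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


def _zscore(features: np.ndarray) -> np.ndarray:
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd == 0] = 1.0
    return (features - mu) / sd


def cluster_habitats(fm: VoxelFeatureMap, k: int, seed: int = 0) -> HabitatMap:
    """Per-sample K-means on Z-scored voxel features.

    k-means++ initialization, 10 restarts, fixed seed.  Clusters are relabeled
    in increasing order of mean windowed intensity so that label 1 is always
    the darkest habitat — the cross-patient correspondence rule.
    """
    if k < 2:
        raise ValueError("k must be ≥ 2")
    n = fm.features.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} tumor voxels")
    X = _zscore(fm.features)
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct feature rows")
    km = KMeans(n_clusters=k, n_init=10, init="k-means++", random_state=seed)
    raw = km.fit_predict(X)

    order = np.argsort([fm.intensity[raw == j].mean() for j in range(k)], kind="stable")
    relabel = np.empty(k, dtype=np.int16)
    relabel[order] = np.arange(1, k + 1)
    lab = relabel[raw]

    grid = np.zeros(fm.shape, dtype=np.int16)
    grid[fm.voxel_index[:, 0], fm.voxel_index[:, 1], fm.voxel_index[:, 2]] = lab
    fractions = np.array([(lab == j).sum() for j in range(1, k + 1)], dtype=np.float64) / n
    return HabitatMap(
        labels=RegionMask(grid, fm.spacing_mm, fm.origin), k=k, fractions=fractions
    )


def select_k(
    feature_maps: list[VoxelFeatureMap],
    k_grid: range | tuple = range(2, 9),
    seed: int = 0,
) -> KSelectionResult:
    """Cohort-wide cluster-count selection.

    For each k, every sample is clustered and its CH index computed on the
    Z-scored features; k* maximizes the per-sample mean CH.  Samples that fail
    to cluster at some k are skipped with a warning; a k succeeding on fewer
    than half the samples is excluded from the argmax.
    """
    k_grid = tuple(int(k) for k in k_grid)
    if len(feature_maps) < 5:
        raise ValueError("k selection needs at least 5 samples")
    per_sample: dict[int, list[float]] = {}
    mean_scores: dict[int, float] = {}
    for k in k_grid:
        scores = []
        for i, fm in enumerate(feature_maps):
            try:
                hab = cluster_habitats(fm, k, seed=seed)
                lab = hab.labels.labels[
                    fm.voxel_index[:, 0], fm.voxel_index[:, 1], fm.voxel_index[:, 2]
                ]
                scores.append(ch_index(_zscore(fm.features), lab))
            except ValueError as exc:
                log.warning("sample %d failed at k=%d: %s", i, k, exc)
        per_sample[k] = scores
        finite = [s for s in scores if np.isfinite(s)]
        if len(scores) >= 0.5 * len(feature_maps) and finite:
            mean_scores[k] = float(np.mean(finite))
    if not mean_scores:
        raise ValueError("no k on the grid clustered at least half the cohort")
    k_star = max(mean_scores, key=lambda k: (mean_scores[k], -k))
    return KSelectionResult(
        k_grid=k_grid, ch_scores=mean_scores, k_star=k_star, per_sample=per_sample
    )
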