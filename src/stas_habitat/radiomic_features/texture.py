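"""Gray-level texture matrices: GLCM, GLRLM, GLSZM.

All three operate on the fixed-bin-count discretized region (gray levels
1..Ng) inside its bounding box.  GLCM and GLRLM aggregate over the 13 unique
3-D directions at distance 1: co-occurrences are accumulated symmetrically
and features are averaged across directions (the common IBSI aggregation);
run matrices are likewise computed per direction and feature values averaged.
GLSZM zones are 26-connected components of constant gray level (a single
direction-free matrix).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EPS = np.finfo(np.float64).tiny

# 13 unique direction offsets at Chebyshev distance 1
DIRECTIONS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]

GLCM_FEATURES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "MCC",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_FEATURES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)


def _shifted_views(arr: np.ndarray, offset: tuple[int, int, int]):
    """Pair of views (arr[p], arr[p + offset]) over the overlap region."""
    sl_a, sl_b = [], []
    for n, d in zip(arr.shape, offset):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int, offset) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction offset."""
    a, b = _shifted_views(levels, offset)
    ma, mb = _shifted_views(mask, offset)
    valid = ma & mb
    flat = (a[valid] - 1) * n_levels + (b[valid] - 1)
    m = np.bincount(flat, minlength=n_levels * n_levels).astype(np.float64)
    m = m.reshape(n_levels, n_levels)
    return m + m.T


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    Ng = P.shape[0]
    i = np.arange(1, Ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = np.sqrt(float(((i - mu_x) ** 2 * px).sum()))
    sig_y = np.sqrt(float(((i - mu_y) ** 2 * py).sum()))

    # p_{x+y}: k = 2..2Ng ; p_{x-y}: k = 0..Ng-1
    ksum = np.arange(2, 2 * Ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * Ng - 1)
    np.add.at(p_sum, (ii + jj).astype(np.int64).ravel() - 2, P.ravel())
    kdiff = np.arange(0, Ng, dtype=np.float64)
    p_diff = np.zeros(Ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(np.int64).ravel(), P.ravel())

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    diff_avg = float((kdiff * p_diff).sum())
    hxy = ent(P.ravel())
    px_py = np.outer(px, py)
    nz = (P > 0) & (px_py > 0)
    hxy1 = float(-(P[nz] * np.log2(px_py[nz])).sum())
    nz2 = px_py > 0
    hxy2 = float(-(px_py[nz2] * np.log2(px_py[nz2])).sum())
    hx, hy = ent(px), ent(py)

    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if Ng > 1 and np.all(px > 0):
        Q = (P / px[:, None]) @ (P / py[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, eig[-2]))) if eig.size > 1 else 1.0
    else:
        # degenerate marginals: fall back to the dominant-component value
        mcc = 1.0

    if sig_x > 0 and sig_y > 0:
        correlation = (float((ii * jj * P).sum()) - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 1.0

    off_diag = np.abs(ii - jj) > 0
    return {
        "Autocorrelation": float((ii * jj * P).sum()),
        "ClusterProminence": float(((ii + jj - mu_x - mu_y) ** 4 * P).sum()),
        "ClusterShade": float(((ii + jj - mu_x - mu_y) ** 3 * P).sum()),
        "ClusterTendency": float(((ii + jj - mu_x - mu_y) ** 2 * P).sum()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((kdiff - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((P / (1.0 + (ii - jj) ** 2 / Ng**2)).sum()),
        "Idn": float((P / (1.0 + np.abs(ii - jj) / Ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((P[off_diag] / (ii - jj)[off_diag] ** 2).sum()),
        "JointAverage": mu_x,
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(P.max()),
        "MCC": mcc,
        "SumAverage": float((ksum * p_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float(((ii - mu_x) ** 2 * P).sum()),
    }


def glcm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    """GLCM features averaged over the 13 directions at distance 1."""
    per_dir = []
    for off in DIRECTIONS:
        m = glcm_matrix(levels, mask, n_levels, off)
        total = m.sum()
        if total > 0:
            per_dir.append(_glcm_features_single(m / total))
    if not per_dir:
        raise ValueError("no voxel pairs in any direction (region too small)")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_FEATURES}


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int, offset) -> np.ndarray:
    """Run-length counts for one direction: rows = gray level, cols = length."""
    # cont[p] = True when p and p+offset are both in-region with equal level
    a, b = _shifted_views(levels, offset)
    ma, mb = _shifted_views(mask, offset)
    cont = np.zeros(levels.shape, dtype=bool)
    sl_a = tuple(
        slice(0, n - d) if d >= 0 else slice(-d, n) for n, d in zip(levels.shape, offset)
    )
    cont[sl_a] = ma & mb & (a == b)

    # a run starts where the predecessor does not continue into the voxel
    prev_cont = np.zeros(levels.shape, dtype=bool)
    sl_b = tuple(
        slice(d, n) if d >= 0 else slice(0, n + d) for n, d in zip(levels.shape, offset)
    )
    prev_cont[sl_b] = cont[sl_a]
    starts = mask & ~prev_cont

    # run length at each start = 1 + longest chain of cont steps; the loop
    # maintains chain_t[p] = cont[p] & cont[p+d] & ... & cont[p+(t-1)d]
    length = np.ones(levels.shape, dtype=np.int64)
    chain = cont.copy()
    while chain.any():
        length += chain
        moved = np.zeros(levels.shape, dtype=bool)
        moved[sl_a] = chain[sl_b]
        chain = chain & moved

    gl = levels[starts] - 1
    rl = length[starts] - 1
    out = np.zeros((n_levels, rl.max() + 1 if rl.size else 1), dtype=np.float64)
    np.add.at(out, (gl, rl), 1.0)
    return out


def _rl_features(R: np.ndarray, n_voxels: int, prefix: str) -> dict[str, float]:
    """Shared gray-level/size weighted emphases for GLRLM and GLSZM."""
    Nr = R.sum()
    i = np.arange(1, R.shape[0] + 1, dtype=np.float64)  # gray level
    j = np.arange(1, R.shape[1] + 1, dtype=np.float64)  # run length / zone size
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = R / Nr
    pg = R.sum(axis=1)
    pr = R.sum(axis=0)
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    p_nz = p[p > 0]

    if prefix == "run":
        names = GLRLM_FEATURES
    else:
        names = GLSZM_FEATURES
    vals = [
        float((R / jj**2).sum() / Nr),
        float((R * jj**2).sum() / Nr),
        float((pg**2).sum() / Nr),
        float((pg**2).sum() / Nr**2),
        float((pr**2).sum() / Nr),
        float((pr**2).sum() / Nr**2),
        float(Nr / n_voxels),
        float(((ii - mu_i) ** 2 * p).sum()),
        float(((jj - mu_j) ** 2 * p).sum()),
        float(-(p_nz * np.log2(p_nz)).sum()),
        float((R / ii**2).sum() / Nr),
        float((R * ii**2).sum() / Nr),
        float((R / (ii**2 * jj**2)).sum() / Nr),
        float((R * ii**2 / jj**2).sum() / Nr),
        float((R * jj**2 / ii**2).sum() / Nr),
        float((R * ii**2 * jj**2).sum() / Nr),
    ]
    return dict(zip(names, vals))


def glrlm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    """GLRLM features averaged over the 13 directions."""
    n_vox = int(mask.sum())
    per_dir = []
    for off in DIRECTIONS:
        R = glrlm_matrix(levels, mask, n_levels, off)
        if R.sum() > 0:
            per_dir.append(_rl_features(R, n_vox, "run"))
    if not per_dir:
        raise ValueError("empty run matrix")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size counts: 26-connected components of constant gray level."""
    structure = np.ones((3, 3, 3), dtype=bool)
    records: list[tuple[int, int]] = []
    for g in range(1, n_levels + 1):
        region = mask & (levels == g)
        if not region.any():
            continue
        lab, n = ndimage.label(region, structure=structure)
        sizes = ndimage.sum_labels(region, lab, index=np.arange(1, n + 1)).astype(int)
        records.extend((g, s) for s in sizes)
    if not records:
        raise ValueError("empty zone matrix")
    max_size = max(s for _, s in records)
    out = np.zeros((n_levels, max_size), dtype=np.float64)
    for g, s in records:
        out[g - 1, s - 1] += 1.0
    return out


def glszm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    R = glszm_matrix(levels, mask, n_levels)
    return _rl_features(R, int(mask.sum()), "zone")
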