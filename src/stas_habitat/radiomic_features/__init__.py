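"""IBSI-style radiomic feature extraction and the cohort feature table.

Each region (intratumoral mask, a peritumoral ring, or one habitat subregion)
yields 88 features on the original image: 14 shape, 18 first-order, 24 GLCM,
16 GLRLM, and 16 GLSZM.  Gray levels are discretized with a fixed bin count
(32) over the region's windowed-intensity range; GLCM/GLRLM aggregate over
the 13 unique 3-D directions at distance 1.

Habitat subregions produced by unsupervised clustering can be absent or tiny
in individual patients; those cells are left missing and filled by
:func:`knn_impute` (nearest training rows on Z-scored complete columns).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..ct_preprocess import CTVolume, RegionMask
from .discretize import DiscretizationSpec, discretize
from .firstorder import FIRSTORDER_FEATURES, firstorder_features
from .shape import SHAPE_FEATURES, shape_features
from .texture import (
    GLCM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    glcm_features,
    glrlm_features,
    glszm_features,
)

log = logging.getLogger(__name__)

FEATURE_CLASSES = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
}

ALL_FEATURE_NAMES = tuple(
    f"{cls}_{name}" for cls, names in FEATURE_CLASSES.items() for name in names
)  # 88 per region

__all__ = [
    "DiscretizationSpec",
    "ALL_FEATURE_NAMES",
    "FEATURE_CLASSES",
    "extract_region_features",
    "extract_all",
    "knn_impute",
]


def extract_region_features(
    ct: CTVolume,
    region: RegionMask,
    spec: DiscretizationSpec | None = None,
) -> dict[str, float]:
    """All 88 features of one region, keyed ``class_FeatureName``.

    Regions with fewer than 2 voxels return an all-missing vector with a
    warning (they feed the imputation stage rather than abort the cohort).
    """
    spec = spec or DiscretizationSpec()
    if not region.same_grid_as(ct):
        raise ValueError("region mask must be aligned with the CT grid")
    mask = region.binary()
    n = int(mask.sum())
    if n < 2:
        log.warning("region with %d voxel(s); emitting missing feature vector", n)
        return {name: np.nan for name in ALL_FEATURE_NAMES}

    # work in the bounding box for the texture matrices
    coords = np.argwhere(mask)
    lo, hi = coords.min(axis=0), coords.max(axis=0) + 1
    sub_mask = mask[tuple(slice(a, b) for a, b in zip(lo, hi))]
    sub_vals = ct.values[tuple(slice(a, b) for a, b in zip(lo, hi))].astype(np.float64)

    voxel_volume = float(np.prod(ct.spacing_mm))
    values = sub_vals[sub_mask]
    levels = np.ones(sub_mask.shape, dtype=np.int64)
    levels[sub_mask] = discretize(values, spec)

    out: dict[str, float] = {}
    for name, value in shape_features(mask, ct.spacing_mm).items():
        out[f"shape_{name}"] = value
    for name, value in firstorder_features(values, voxel_volume, spec).items():
        out[f"firstorder_{name}"] = value
    for name, value in glcm_features(levels, sub_mask, spec.bins).items():
        out[f"glcm_{name}"] = value
    for name, value in glrlm_features(levels, sub_mask, spec.bins).items():
        out[f"glrlm_{name}"] = value
    for name, value in glszm_features(levels, sub_mask, spec.bins).items():
        out[f"glszm_{name}"] = value
    return out


def extract_all(
    cases: list[tuple[str, CTVolume, dict[str, RegionMask]]],
    spec: DiscretizationSpec | None = None,
) -> pd.DataFrame:
    """Feature table for a cohort: one row per patient, one 88-feature block
    per region, columns ``{region}_{class}_{FeatureName}``.

    ``cases`` holds ``(patient_id, windowed_ct, {region_tag: mask})``.  Region
    tags are e.g. ``intra``, ``peri1``, ``peri3``, ``peri5``, ``hab1..habk``
    and must be consistent across patients.  A patient missing a region gets
    missing cells for that block (flagged, not dropped).
    """
    spec = spec or DiscretizationSpec()
    region_tags: list[str] = []
    for _, _, regions in cases:
        for tag in regions:
            if tag not in region_tags:
                region_tags.append(tag)

    rows = {}
    for pid, ct, regions in cases:
        row: dict[str, float] = {}
        for tag in region_tags:
            mask = regions.get(tag)
            if mask is None:
                log.warning("patient %s missing region %r; cells left missing", pid, tag)
                feats = {name: np.nan for name in ALL_FEATURE_NAMES}
            else:
                feats = extract_region_features(ct, mask, spec)
            row.update({f"{tag}_{k}": v for k, v in feats.items()})
        rows[pid] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "PatientID"
    return table


def knn_impute(
    table: pd.DataFrame,
    train_index: pd.Index | list,
    k_neighbors: int = 5,
) -> pd.DataFrame:
    """Fill missing cells with the mean of the nearest training rows.

    Distances are Euclidean on the complete columns, Z-scored with training
    statistics; the neighbour pool is the training split only (never
    validation/test rows), and the same pool imputes every split.
    """
    if table.isna().all(axis=0).any():
        bad = table.columns[table.isna().all(axis=0)]
        raise ValueError(f"fully-missing column(s): {list(bad[:5])}")
    out = table.copy()
    train = table.loc[train_index]
    complete_cols = table.columns[table.notna().all(axis=0)]
    if len(complete_cols) == 0:
        raise ValueError("no complete columns to measure neighbour distance on")

    mu = train[complete_cols].mean(axis=0)
    sd = train[complete_cols].std(axis=0, ddof=0).replace(0.0, 1.0)
    z_all = ((table[complete_cols] - mu) / sd).to_numpy(dtype=np.float64)
    z_train = ((train[complete_cols] - mu) / sd).to_numpy(dtype=np.float64)
    train_pos = {pid: i for i, pid in enumerate(train.index)}

    for ridx, pid in enumerate(table.index):
        missing = table.columns[table.iloc[ridx].isna()]
        if len(missing) == 0:
            continue
        d2 = ((z_train - z_all[ridx]) ** 2).sum(axis=1)
        if pid in train_pos:  # a training row never counts itself
            d2[train_pos[pid]] = np.inf
        nearest = train.index[np.argsort(d2, kind="stable")[:k_neighbors]]
        for col in missing:
            donors = train.loc[nearest, col].dropna()
            if donors.empty:  # fall back to all observed training values
                donors = train[col].dropna()
            out.loc[pid, col] = float(donors.mean())
    return out
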