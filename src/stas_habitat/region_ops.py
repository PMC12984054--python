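"""Peritumoral ring construction by spacing-aware Euclidean dilation.

Rings at 1/3/5 mm from the tumor boundary are built from a Euclidean distance
transform in physical units (exact mm semantics even at anisotropic spacing),
then intersected with a lung mask so chest wall and mediastinum never enter a
ring.  Distances are measured to the voxel-centre set of the tumor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ct_preprocess import CTVolume, RegionMask


@dataclass
class RingSpec:
    """A peritumoral shell: everything within ``distance_mm`` of the tumor
    surface, optionally intersected with ``exclude_mask`` (the lung)."""

    distance_mm: float
    exclude_mask: RegionMask | None = None

    def __post_init__(self) -> None:
        if self.distance_mm <= 0:
            raise ValueError("ring distance must be positive")


def dilate_mask(tumor: RegionMask, distance_mm: float) -> RegionMask:
    """Dilate a binary mask by a physical distance.

    Output voxels are those whose Euclidean distance to the tumor voxel-centre
    set is ≤ ``distance_mm``, together with the tumor itself.
    """
    if distance_mm < 0:
        raise ValueError("distance must be non-negative")
    binary = tumor.binary()
    if not binary.any():
        raise ValueError("cannot dilate an empty mask")
    dist = ndimage.distance_transform_edt(~binary, sampling=tumor.spacing_mm)
    out = dist <= distance_mm + 1e-9
    return RegionMask(out.astype(np.int16), tumor.spacing_mm, tumor.origin)


def peritumoral_ring(tumor: RegionMask, spec: RingSpec, case_id: str = "") -> RegionMask:
    """ring = (dilate(tumor, d) \\ tumor) ∩ exclude_mask.

    Raises if the ring is empty after exclusion (e.g. a tumor buried in the
    chest wall), naming the case.
    """
    dilated = dilate_mask(tumor, spec.distance_mm)
    ring = dilated.binary() & ~tumor.binary()
    if spec.exclude_mask is not None:
        if not spec.exclude_mask.same_grid_as(tumor):
            raise ValueError("exclude_mask is not aligned with the tumor mask")
        ring &= spec.exclude_mask.binary()
    if not ring.any():
        raise ValueError(
            f"ring vanished at {spec.distance_mm} mm after exclusion"
            + (f" (case {case_id})" if case_id else "")
        )
    return RegionMask(ring.astype(np.int16), tumor.spacing_mm, tumor.origin)


def lung_mask_from_hu(ct: CTVolume, threshold_hu: float = -300.0) -> RegionMask:
    """Heuristic lung mask for real data: HU below threshold, largest
    connected component, holes (tumor included) filled."""
    low = ct.values < threshold_hu
    lab, n = ndimage.label(low)
    if n == 0:
        raise ValueError("no voxels below threshold; not a lung CT?")
    largest = np.argmax(ndimage.sum_labels(low, lab, index=range(1, n + 1))) + 1
    lung = ndimage.binary_fill_holes(lab == largest)
    return RegionMask(lung.astype(np.int16), ct.spacing_mm, ct.origin)
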