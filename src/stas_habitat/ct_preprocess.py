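"""Volume containers, NIfTI IO, isotropic resampling, and lung-window normalization.

CT intensities are in Hounsfield Units (HU).  Before feature work every volume
is resampled to isotropic 1 mm voxels with B-spline interpolation (masks with
nearest-neighbour interpolation) and intensities are normalized with a lung
window — width/level 1500/−500 HU, mapping [−1250, 250] HU onto [0, 1].

Conventions: voxel indices are 0-based, arrays are indexed (x, y, z) matching
the NIfTI on-disk order, world coordinates follow the NIfTI affine, all
distances are in millimetres.  Out-of-field values created by resampling are
filled with −1024 HU (air).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

log = logging.getLogger(__name__)

AIR_HU = -1024.0


@dataclass
class CTVolume:
    """A 3-D scalar CT grid with physical geometry.

    Parameters
    ----------
    values : ndarray
        3-D array of intensities (HU, or [0, 1] after windowing).
    spacing_mm : tuple of float
        Voxel edge lengths along each array axis, strictly positive.
    origin : tuple of float
        World coordinate of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("CTVolume requires a 3-D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CTVolume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class RegionMask:
    """Integer label grid aligned to a :class:`CTVolume` (0 = background)."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("RegionMask requires a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("mask labels must be integers")
            self.labels = np.round(self.labels).astype(np.int16)
        if self.labels.min() < 0:
            raise ValueError("mask labels must be non-negative")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def binary(self) -> np.ndarray:
        return self.labels > 0

    def same_grid_as(self, other: "CTVolume | RegionMask", atol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class WindowSpec:
    """Display-window normalization: HU -> [0, 1].

    The default is the lung window (width 1500 HU, level −500 HU).
    """

    width: float = 1500.0
    level: float = -500.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")

    @property
    def lower(self) -> float:
        return self.level - self.width / 2.0

    @property
    def upper(self) -> float:
        return self.level + self.width / 2.0


# ---------------------------------------------------------------------------
# SimpleITK bridging


def _to_sitk(values: np.ndarray, spacing: tuple, origin: tuple) -> sitk.Image:
    # SimpleITK uses (z, y, x) array order; transpose so axis 0 of our array
    # stays axis 0 of the physical image.
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def resample_isotropic(
    volume: CTVolume | RegionMask,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    order: int = 3,
) -> CTVolume | RegionMask:
    """Resample onto a grid with the requested spacing, preserving extent.

    ``order=3`` uses B-spline interpolation (intensities); ``order=0`` uses
    nearest-neighbour (masks).  The output grid covers the physical extent of
    the input; voxels that fall outside it take −1024 HU (air) for intensity
    volumes and 0 for masks.
    """
    if order not in (0, 3):
        raise ValueError("order must be 0 (masks) or 3 (intensities)")
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")

    is_mask = isinstance(volume, RegionMask)
    values = volume.labels.astype(np.float32) if is_mask else volume.values
    in_spacing = volume.spacing_mm

    new_shape = tuple(
        int(round(n * s_in / s_out))
        for n, s_in, s_out in zip(values.shape, in_spacing, target_spacing)
    )
    if any(n < 1 for n in new_shape):
        raise ValueError(f"target spacing {target_spacing} collapses an axis to zero length")

    img = _to_sitk(values, in_spacing, volume.origin)
    resampler = sitk.ResampleImageFilter()
    resampler.SetOutputSpacing(target_spacing)
    resampler.SetSize(tuple(int(n) for n in new_shape))
    resampler.SetOutputOrigin(volume.origin)
    resampler.SetOutputDirection(img.GetDirection())
    resampler.SetInterpolator(sitk.sitkNearestNeighbor if order == 0 else sitk.sitkBSpline)
    resampler.SetDefaultPixelValue(0.0 if is_mask else AIR_HU)
    arr, spacing, origin = _from_sitk(resampler.Execute(img))

    if is_mask:
        out = np.round(arr).astype(volume.labels.dtype)
        # nearest-neighbour cannot invent labels, but guard against fp round-off
        out[~np.isin(out, np.unique(volume.labels))] = 0
        return RegionMask(out, spacing, origin)
    return CTVolume(arr, spacing, origin)


def apply_window(volume: CTVolume, spec: WindowSpec | None = None) -> CTVolume:
    """Clip-and-scale intensities into [0, 1] by the display window.

    output = clip((HU − (level − width/2)) / width, 0, 1); monotone
    non-decreasing in HU.
    """
    spec = spec or WindowSpec()
    scaled = np.clip((volume.values - spec.lower) / spec.width, 0.0, 1.0)
    return replace(volume, values=scaled.astype(np.float32))


# ---------------------------------------------------------------------------
# NIfTI IO


def save_nifti(obj: CTVolume | RegionMask, path: str | Path) -> Path:
    """Write a volume or mask as NIfTI-1 with a diagonal affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, RegionMask):
        data = obj.labels.astype(np.int16)
    else:
        data = obj.values.astype(np.float32)
    affine = np.diag(list(obj.spacing_mm) + [1.0])
    affine[:3, 3] = obj.origin
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing NIfTI file: {path}")
    img = nib.load(str(path))
    # canonical orientation so permuted-axis metadata maps onto one convention
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, spacing, origin


def load_volume(path: str | Path) -> CTVolume:
    data, spacing, origin = _load_nifti(path)
    return CTVolume(data.astype(np.float32), spacing, origin)


def load_mask(path: str | Path) -> RegionMask:
    data, spacing, origin = _load_nifti(path)
    return RegionMask(np.round(data).astype(np.int16), spacing, origin)


def load_case(
    ct_path: str | Path,
    mask_path: str | Path,
    lung_path: str | Path | None = None,
) -> tuple[CTVolume, RegionMask, RegionMask | None]:
    """Load a CT + tumor mask (+ optional lung mask) as aligned grids.

    A mask on a mismatched grid is resampled onto the CT grid with
    nearest-neighbour interpolation and a logged warning.  Origins that
    disagree by more than 5 mm, or an empty tumor mask, are errors.
    """
    ct = load_volume(ct_path)

    def _align(mask: RegionMask, name: str) -> RegionMask:
        if np.any(np.abs(np.array(mask.origin) - np.array(ct.origin)) > 5.0):
            raise ValueError(
                f"{name} origin {mask.origin} is >5 mm from CT origin {ct.origin}"
            )
        if not mask.same_grid_as(ct):
            warnings.warn(
                f"{name} grid differs from CT grid; resampling with nearest-neighbour",
                stacklevel=3,
            )
            mask = resample_isotropic(mask, ct.spacing_mm, order=0)
            if mask.shape != ct.shape:  # pad/crop residual one-voxel mismatch
                fixed = np.zeros(ct.shape, dtype=mask.labels.dtype)
                sl = tuple(slice(0, min(a, b)) for a, b in zip(ct.shape, mask.shape))
                fixed[sl] = mask.labels[sl]
                mask = RegionMask(fixed, ct.spacing_mm, ct.origin)
        return mask

    tumor = _align(load_mask(mask_path), "tumor mask")
    if not tumor.binary().any():
        raise ValueError(f"empty ROI in {mask_path}")
    lung = _align(load_mask(lung_path), "lung mask") if lung_path is not None else None
    return ct, tumor, lung
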