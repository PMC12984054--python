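"""Phantom CT cohorts with planted habitat structure and a known STAS model.

Each phantom patient is a 3-D chest patch: lung-density parenchyma
(N(−800, 30²) HU), an optional chest-wall slab (+40 ± 10 HU) on one volume
face, and a solid ellipsoidal tumor ≤ 2 cm whose interior is partitioned into
``k_true`` concentric texture subregions (core → rim) with per-subregion HU
mean, noise SD, and texture correlation length.  A peritumoral shell carries
extra correlated noise whose amplitude tracks a latent "peritumoral texture
score".

The STAS label is drawn from a logistic model on three standardized latent
covariates — mediastinal-window tumor size, the volume fraction of the rim
subregion, and the peritumoral texture score — so downstream models have a
known signal to recover.  Clinical covariates without a planted effect (sex,
smoking, tumor markers, CT signs) are Bernoulli draws at the marginal
frequencies of the reference training cohort
(:mod:`~stas_habitat.reference_cohort`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from . import reference_cohort as ref
from .ct_preprocess import CTVolume, RegionMask, load_mask, load_volume, save_nifti

log = logging.getLogger(__name__)

CLINICAL_COLUMNS = [
    "PatientID",
    "Age (Years)",
    "Lwts (mm)",
    "Mwts (mm)",
    "Sex",
    "Smoking history",
    "CEA (ng/mL)",
    "SCCA (ng/mL)",
    "NSE (ng/mL)",
    "CYFRA (ng/mL)",
    "Location",
    "Lobulation",
    "Spiculation",
    "Bronchial cut-off",
    "Air bronchogram",
    "Vacuole",
    "STAS",
]

_LOCATIONS = ("RUL", "RML", "RLL", "LUL", "LLL")
# training-cohort location frequencies
_LOCATION_P = (72 / 217, 16 / 217, 43 / 217, 43 / 217, 43 / 217)


@dataclass
class StasCoefficients:
    """Logistic STAS model on standardized covariates.

    P(STAS) = expit(intercept + size·z_size + rim_fraction·z_rim +
    peritumoral_texture·z_peri) where the z's are the patient's latent
    standard-normal covariate scores.  The default intercept puts the
    prevalence near the reference cohort's 37.8% when the effects are active;
    the default effect sizes make the imaging signals (habitat composition,
    peritumoral texture) markedly stronger than clinical size alone, the
    ordering the reference study reports.
    """

    intercept: float = -0.7
    size: float = 0.3
    rim_fraction: float = 1.5
    peritumoral_texture: float = 1.2

    def as_array(self) -> np.ndarray:
        return np.array([self.size, self.rim_fraction, self.peritumoral_texture])


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 40
    seed: int = 0
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    parenchyma_hu: tuple[float, float] = (-800.0, 30.0)
    # (mean HU, noise SD HU, texture correlation length in voxels), core -> rim
    tumor_hu_by_subregion: tuple[tuple[float, float, float], ...] = (
        (60.0, 15.0, 1.0),
        (10.0, 25.0, 2.0),
        (-80.0, 40.0, 3.0),
    )
    k_true: int = 3
    diameter_range_mm: tuple[float, float] = (10.0, 20.0)
    stas_coefficients: StasCoefficients = field(default_factory=StasCoefficients)
    chest_wall: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be ≥ 2")
        if self.k_true < 1:
            raise ValueError("k_true must be ≥ 1")
        if len(self.tumor_hu_by_subregion) != self.k_true:
            raise ValueError("tumor_hu_by_subregion must have k_true entries")
        if any(n <= 0 for n in self.volume_shape):
            raise ValueError("volume_shape must be positive")
        if self.parenchyma_hu[1] < 0 or any(s[1] < 0 for s in self.tumor_hu_by_subregion):
            raise ValueError("noise SDs must be ≥ 0")
        lo, hi = self.diameter_range_mm
        if not (0 < lo < hi <= 20.0):
            raise ValueError("diameter range must lie in (0, 20] mm (tumors ≤ 2 cm)")


@dataclass
class PhantomPatient:
    """One phantom case; image fields are None for scalar-only cohorts."""

    patient_id: str
    ct: CTVolume | None
    tumor_mask: RegionMask | None
    lung_mask: RegionMask | None
    true_subregion_labels: RegionMask | None
    clinical: dict
    stas: int
    latents: dict = field(default_factory=dict)


def _smooth_unit_noise(rng: np.random.Generator, shape, corr_len: float) -> np.ndarray:
    """Gaussian noise field smoothed at the given correlation length and
    rescaled to unit variance (one knob for texture scale)."""
    g = rng.standard_normal(shape)
    if corr_len > 0:
        g = ndimage.gaussian_filter(g, sigma=corr_len)
        sd = g.std()
        if sd > 0:
            g /= sd
    return g


def _render_patient(
    idx: int,
    config: PhantomConfig,
    scalar_rng: np.random.Generator,
    image_rng: np.random.Generator | None,
) -> PhantomPatient:
    """One phantom patient.

    ``scalar_rng`` drives every scalar draw (latents, label, clinical fields,
    geometry parameters); ``image_rng`` drives the voxel fields.  Passing
    ``image_rng=None`` skips rendering entirely — the clinical table and
    label are bit-identical either way, which lets label-model studies run at
    cohort sizes where rendering would dominate.
    """
    rng = scalar_rng
    shape = tuple(config.volume_shape)
    spacing = np.asarray(config.voxel_spacing_mm, dtype=float)
    coeff = config.stas_coefficients

    # latent standardized covariates of the label model
    z_size, z_rim, z_peri = rng.standard_normal(3)

    # clinical sizes: mediastinal window (solid core) tracks z_size; the lung
    # window reads ~2.7 mm larger and sets the rendered diameter
    mwts = float(np.clip(11.6 + 3.9 * z_size, 3.0, 19.0))
    lwts = float(np.clip(mwts + 2.7 + rng.normal(0, 1.2), 4.0, 20.0))
    lo, hi = config.diameter_range_mm
    diameter = float(np.clip(lwts, lo, hi))

    eta = coeff.intercept + coeff.size * z_size + coeff.rim_fraction * z_rim
    eta += coeff.peritumoral_texture * z_peri
    stas = int(rng.random() < expit(eta))

    # geometry scalars (still scalar randomness, independent of rendering)
    semi = np.array([diameter / 2.0, 0.0, 0.0])
    semi[1] = semi[0] * rng.uniform(0.75, 1.0)
    semi[2] = semi[0] * rng.uniform(0.75, 1.0)
    rng.shuffle(semi)
    jitter = rng.uniform(-4, 4, size=3)
    band_axis = rng.standard_normal(3)
    band_axis /= np.linalg.norm(band_axis)

    clinical = {
        "PatientID": f"P{idx:04d}",
        "Age (Years)": round(float(np.clip(rng.normal(62.8, 8.1), 30, 90)), 1),
        "Lwts (mm)": round(lwts, 1),
        "Mwts (mm)": round(mwts, 1),
        "Sex": "Male" if rng.random() < ref.marginal_rate("Sex") else "Female",
        "Smoking history": "Yes" if rng.random() < ref.marginal_rate("Smoking history") else "No",
        "CEA (ng/mL)": ">5.0" if rng.random() < ref.marginal_rate("CEA (ng/mL)") else "≤5.0",
        "SCCA (ng/mL)": ">1.5" if rng.random() < ref.marginal_rate("SCCA (ng/mL)") else "≤1.5",
        "NSE (ng/mL)": ">17.0" if rng.random() < ref.marginal_rate("NSE (ng/mL)") else "≤17.0",
        "CYFRA (ng/mL)": ">3.3" if rng.random() < ref.marginal_rate("CYFRA (ng/mL)") else "≤3.3",
        "Location": _LOCATIONS[rng.choice(len(_LOCATIONS), p=_LOCATION_P)],
        "Lobulation": "Present" if rng.random() < ref.marginal_rate("Lobulation") else "Absent",
        "Spiculation": "Present" if rng.random() < ref.marginal_rate("Spiculation") else "Absent",
        "Bronchial cut-off": "Present"
        if rng.random() < ref.marginal_rate("Bronchial cut-off")
        else "Absent",
        "Air bronchogram": "Present"
        if rng.random() < ref.marginal_rate("Air bronchogram")
        else "Absent",
        "Vacuole": "Present" if rng.random() < ref.marginal_rate("Vacuole") else "Absent",
        "STAS": stas,
    }
    latents = {"z_size": float(z_size), "z_rim": float(z_rim), "z_peri": float(z_peri)}
    sp = tuple(float(s) for s in spacing)

    if image_rng is None:
        return PhantomPatient(
            patient_id=clinical["PatientID"], ct=None, tumor_mask=None, lung_mask=None,
            true_subregion_labels=None, clinical=clinical, stas=stas, latents=latents,
        )

    # ----- voxel rendering (image randomness only) -----
    img = image_rng
    # parenchyma (i.i.d. so the marginal HU histogram is exactly normal)
    p_mean, p_sd = config.parenchyma_hu
    ct = img.normal(p_mean, p_sd, size=shape)
    lung = np.ones(shape, dtype=bool)
    if config.chest_wall:
        slab = max(3, int(round(4.0 / spacing[0])))
        ct[-slab:, :, :] = img.normal(40.0, 10.0, size=(slab,) + shape[1:])
        lung[-slab:, :, :] = False

    extent_vox = semi / spacing
    margin = extent_vox + 6.0 / spacing  # keep shell + tumor clear of borders/slab
    if np.any(margin > np.array(shape) / 2.0):
        raise ValueError("volume_shape too small for the configured tumor diameters")
    centre = np.clip(
        np.array(shape) / 2.0 + jitter, margin, np.array(shape) - 1 - margin
    )

    # render the tumor + shell inside a bounding box (the rest of the volume
    # only carries parenchyma); keeps the textured-field synthesis cheap
    pad = extent_vox + 5.0 / spacing + 4
    lo = np.maximum(np.floor(centre - pad).astype(int), 0)
    hi = np.minimum(np.ceil(centre + pad).astype(int) + 1, shape)
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    bshape = tuple(int(b - a) for a, b in zip(lo, hi))
    bgrids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")

    r2 = sum(
        ((g - c) * s / a) ** 2 for g, c, s, a in zip(bgrids, centre, spacing, semi)
    )
    btumor = r2 <= 1.0
    n_tumor = int(btumor.sum())
    if n_tumor < 20 * config.k_true:
        raise ValueError(
            f"tumor of {n_tumor} voxels cannot carry {config.k_true} "
            "distinguishable subregions"
        )

    # banded subregions: the tumor is split into k_true parallel slabs along a
    # random axis, ordered by decreasing HU, with smoothly perturbed
    # boundaries.  Bands keep internal boundary area small (no junction ever
    # joins non-adjacent HU plateaus), so the 5³ feature windows mostly sit
    # inside one subregion and boundary windows interpolate between
    # neighbouring plateaus.  The volume fraction of the last (darkest)
    # subregion carries the planted z_rim effect.
    last_frac = float(np.clip(0.35 + 0.12 * z_rim, 0.10, 0.62))
    blabels = np.zeros(bshape, dtype=np.int16)
    if config.k_true > 1:
        other = (1.0 - last_frac) / (config.k_true - 1)
        cum = [other * j for j in range(1, config.k_true)]
        u = sum(
            b * (g - c) * s for b, g, c, s in zip(band_axis, bgrids, centre, spacing)
        )  # mm along the band axis
        perturb = 0.12 * diameter * _smooth_unit_noise(img, bshape, 2.5)
        tv = (u + perturb)[btumor]
        cuts = [np.quantile(tv, q) for q in cum]
        blabels[btumor] = np.digitize(tv, cuts) + 1
    else:
        blabels[btumor] = 1

    # per-subregion textured HU
    bct = ct[box]
    for j, (mu, sd, corr) in enumerate(config.tumor_hu_by_subregion, start=1):
        region = blabels == j
        if region.any():
            bct[region] = mu + sd * _smooth_unit_noise(img, bshape, corr)[region]

    # peritumoral shell (≤ 5 mm) with texture amplitude tied to z_peri
    dist = ndimage.distance_transform_edt(~btumor, sampling=spacing)
    shell = (dist > 0) & (dist <= 5.0) & lung[box]
    shell_sd = max(1.0, 14.0 + 7.0 * z_peri)
    bct[shell] += shell_sd * _smooth_unit_noise(img, bshape, 1.5)[shell]
    ct[box] = bct

    tumor = np.zeros(shape, dtype=bool)
    tumor[box] = btumor
    labels = np.zeros(shape, dtype=np.int16)
    labels[box] = blabels

    return PhantomPatient(
        patient_id=clinical["PatientID"],
        ct=CTVolume(ct.astype(np.float32), sp),
        tumor_mask=RegionMask(tumor.astype(np.int16), sp),
        lung_mask=RegionMask(lung.astype(np.int16), sp),
        true_subregion_labels=RegionMask(labels, sp),
        clinical=clinical,
        stas=stas,
        latents=latents,
    )


def generate_cohort(
    config: PhantomConfig, render_images: bool = True
) -> list[PhantomPatient]:
    """Render a deterministic phantom cohort (bit-identical given the seed).

    With ``render_images=False`` only the clinical table, labels, and latents
    are produced (volumes/masks are None); the scalar draws are identical to
    the rendered cohort's.
    """
    out = []
    for i, ss in enumerate(np.random.SeedSequence(config.seed).spawn(config.n_patients)):
        scalar_ss, image_ss = ss.spawn(2)
        out.append(
            _render_patient(
                i,
                config,
                np.random.default_rng(scalar_ss),
                np.random.default_rng(image_ss) if render_images else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# disk round-trip


def cohort_to_disk(
    patients: list[PhantomPatient],
    directory: str | Path,
    seed: int | None = None,
    overwrite: bool = False,
) -> Path:
    """Write one NIfTI per volume/mask, a clinical CSV, and a JSON manifest."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    directory.mkdir(parents=True, exist_ok=True)

    entries = []
    rows = []
    for p in patients:
        files = {
            "ct": f"{p.patient_id}_ct.nii.gz",
            "tumor_mask": f"{p.patient_id}_tumor.nii.gz",
            "lung_mask": f"{p.patient_id}_lung.nii.gz",
            "true_subregions": f"{p.patient_id}_subregions.nii.gz",
        }
        save_nifti(p.ct, directory / files["ct"])
        save_nifti(p.tumor_mask, directory / files["tumor_mask"])
        save_nifti(p.lung_mask, directory / files["lung_mask"])
        save_nifti(p.true_subregion_labels, directory / files["true_subregions"])
        entries.append({"patient_id": p.patient_id, "files": files, "stas": p.stas})
        rows.append(p.clinical)

    clinical_path = directory / "clinical.csv"
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(clinical_path, index=False)
    manifest = {
        "patients": entries,
        "clinical_table": clinical_path.name,
        "seed": seed,
        "n_patients": len(patients),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_cohort(manifest_path: str | Path) -> list[PhantomPatient]:
    """Reload a cohort written by :func:`cohort_to_disk`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    directory = manifest_path.parent
    clinical = pd.read_csv(directory / manifest["clinical_table"])
    clinical = clinical.set_index("PatientID", drop=False)

    patients = []
    for entry in manifest["patients"]:
        pid = entry["patient_id"]
        for key, fname in entry["files"].items():
            if not (directory / fname).exists():
                raise FileNotFoundError(f"patient {pid}: missing file {fname}")
        f = entry["files"]
        patients.append(
            PhantomPatient(
                patient_id=pid,
                ct=load_volume(directory / f["ct"]),
                tumor_mask=load_mask(directory / f["tumor_mask"]),
                lung_mask=load_mask(directory / f["lung_mask"]),
                true_subregion_labels=load_mask(directory / f["true_subregions"]),
                clinical=clinical.loc[pid].to_dict(),
                stas=int(entry["stas"]),
            )
        )
    return patients


def clinical_frame(patients: list[PhantomPatient]) -> pd.DataFrame:
    """Clinical table (Table-1 column layout) for a cohort in memory."""
    return pd.DataFrame([p.clinical for p in patients], columns=CLINICAL_COLUMNS)
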