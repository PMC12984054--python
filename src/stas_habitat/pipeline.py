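"""End-to-end orchestration: phantoms (or loaded cases) → preprocessing →
rings → habitats → features → selection → models → evaluation.

All randomness funnels through one seed recorded in the run outputs; reruns
with the same config reproduce every deterministic stage bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation_stats as ev
from . import model_zoo as mz
from .ct_preprocess import WindowSpec, apply_window, resample_isotropic
from .feature_selection import run_cascade
from .habitat_clustering import cluster_habitats, local_feature_map, select_k
from .radiomic_features import DiscretizationSpec, extract_all, knn_impute
from .region_ops import RingSpec, peritumoral_ring
from .synthetic_cohort import PhantomConfig, PhantomPatient, clinical_frame, generate_cohort

log = logging.getLogger(__name__)

NUMERIC_CLINICAL = ("Age (Years)", "Lwts (mm)", "Mwts (mm)")
BINARY_CLINICAL = {
    "Sex": "Male",
    "Smoking history": "Yes",
    "CEA (ng/mL)": ">5.0",
    "SCCA (ng/mL)": ">1.5",
    "NSE (ng/mL)": ">17.0",
    "CYFRA (ng/mL)": ">3.3",
    "Lobulation": "Present",
    "Spiculation": "Present",
    "Bronchial cut-off": "Present",
    "Air bronchogram": "Present",
    "Vacuole": "Present",
}


@dataclass
class RunConfig:
    """A full pipeline run over a synthetic cohort.

    ``split_ratios`` defaults to the study's 7:3 train/validation split; an
    external test cohort of ``n_test`` phantoms is generated from a separate
    stream of the same seed (set to 0 to skip).
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_test: int = 24
    split_ratios: tuple[float, float] = (0.7, 0.3)
    ring_distances_mm: tuple[float, ...] = (1.0, 3.0, 5.0)
    k_grid: tuple[int, ...] = tuple(range(2, 9))
    fixed_k: int | None = None
    window: WindowSpec = field(default_factory=WindowSpec)
    mrmr_m: int = 30
    lasso_folds: int = 10
    regions: tuple[str, ...] = ("Intra", "Peri1mm", "Peri3mm", "Peri5mm", "Habitat")
    seed: int = 0
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


def split_cohort(
    labels: pd.Series,
    ratios: tuple[float, float] = (0.7, 0.3),
    seed: int = 0,
    stratify: bool = True,
) -> pd.Series:
    """Assign each patient to 'train' or 'validation'.

    Stratified by label (per-class rounding, so 310 patients at 7:3 with the
    reference prevalence give 217/93); plain random available by flag.
    """
    rng = np.random.default_rng(seed)
    n = len(labels)
    assign = pd.Series("validation", index=labels.index, name="split")
    if stratify:
        for value in sorted(labels.unique()):
            ids = labels.index[labels == value].to_numpy()
            if len(ids) < 2:
                raise ValueError(f"class {value} has fewer than 2 members")
            n_train = int(round(len(ids) * ratios[0]))
            chosen = rng.choice(ids, size=n_train, replace=False)
            assign.loc[chosen] = "train"
    else:
        chosen = rng.choice(labels.index.to_numpy(), int(round(n * ratios[0])), replace=False)
        assign.loc[chosen] = "train"
    return assign


def clinical_design(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix from the Table-1-style clinical frame:
    continuous variables as-is, binaries as 0/1 indicators, location one-hot
    against the RUL reference."""
    out = pd.DataFrame(index=clinical.index)
    for col in NUMERIC_CLINICAL:
        out[col] = clinical[col].astype(float)
    for col, positive in BINARY_CLINICAL.items():
        out[col] = (clinical[col] == positive).astype(int)
    for loc in ("RML", "RLL", "LUL", "LLL"):
        out[f"Location[{loc}]"] = (clinical["Location"] == loc).astype(int)
    return out


# ---------------------------------------------------------------------------
# stage helpers (also used piecemeal by the analysis scripts and tests)


def preprocess_patients(
    patients: list[PhantomPatient], window: WindowSpec | None = None
) -> list[PhantomPatient]:
    """Resample to 1 mm isotropic if needed and lung-window the CT."""
    window = window or WindowSpec()
    out = []
    for p in patients:
        ct = p.ct
        if not np.allclose(ct.spacing_mm, (1.0, 1.0, 1.0)):
            ct = resample_isotropic(ct, (1.0, 1.0, 1.0), order=3)
            p = PhantomPatient(
                patient_id=p.patient_id,
                ct=ct,
                tumor_mask=resample_isotropic(p.tumor_mask, (1.0, 1.0, 1.0), order=0),
                lung_mask=resample_isotropic(p.lung_mask, (1.0, 1.0, 1.0), order=0),
                true_subregion_labels=resample_isotropic(
                    p.true_subregion_labels, (1.0, 1.0, 1.0), order=0
                ),
                clinical=p.clinical,
                stas=p.stas,
                latents=p.latents,
            )
        p.ct = apply_window(p.ct, window)
        out.append(p)
    return out


def build_regions(
    patients: list[PhantomPatient],
    ring_distances_mm=(1.0, 3.0, 5.0),
    k: int = 3,
    seed: int = 0,
) -> tuple[list[tuple[str, object, dict]], list]:
    """Rings + habitat subregions for every (windowed) patient.

    Returns extract_all-ready cases and the per-patient habitat maps.
    """
    cases = []
    habitat_maps = []
    for p in patients:
        regions = {"intra": p.tumor_mask}
        for d in ring_distances_mm:
            spec = RingSpec(distance_mm=d, exclude_mask=p.lung_mask)
            regions[f"peri{d:g}"] = peritumoral_ring(p.tumor_mask, spec, p.patient_id)
        fm = local_feature_map(p.ct, p.tumor_mask)
        hab = cluster_habitats(fm, k=k, seed=seed)
        habitat_maps.append(hab)
        for j in range(1, k + 1):
            sub = (hab.labels.labels == j).astype(np.int16)
            regions[f"hab{j}"] = type(p.tumor_mask)(
                sub, p.tumor_mask.spacing_mm, p.tumor_mask.origin
            )
        cases.append((p.patient_id, p.ct, regions))
    return cases, habitat_maps


REGION_MODELS = {
    "Intra": ("intra_",),
    "Peri1mm": ("peri1_",),
    "Peri3mm": ("peri3_",),
    "Peri5mm": ("peri5_",),
    "Habitat": ("hab",),
}


def region_columns(table: pd.DataFrame, region: str) -> list[str]:
    prefixes = REGION_MODELS[region]
    return [c for c in table.columns if any(c.startswith(p) for p in prefixes)]


@dataclass
class RunResult:
    models: dict[str, object]
    predictions: dict[str, pd.DataFrame]
    reports: dict[str, dict]
    selection: dict[str, object]
    feature_table: pd.DataFrame
    labels: pd.Series
    split: pd.Series
    k_star: int
    regression: object = None


def run_all(config: RunConfig) -> RunResult:
    """Execute the full workflow on a synthetic cohort.

    Stages: simulate → preprocess → rings → habitat clustering (k selected by
    mean CH unless ``fixed_k``) → feature extraction → KNN imputation →
    per-region selection cascade → five-family training per region + clinical
    model → stacked Combined model → per-model evaluation battery.
    """
    rng_seed = int(config.seed)
    patients = generate_cohort(config.phantom)
    patients = preprocess_patients(patients, config.window)
    clinical = clinical_frame(patients).set_index("PatientID")
    labels = clinical["STAS"].astype(int)
    split = split_cohort(labels, config.split_ratios, seed=rng_seed)

    if config.n_test > 0:
        test_cfg = PhantomConfig(
            **{
                **config.phantom.__dict__,
                "n_patients": config.n_test,
                "seed": config.phantom.seed + 10_007,
            }
        )
        test_patients = preprocess_patients(generate_cohort(test_cfg), config.window)
        test_clin = clinical_frame(test_patients).set_index("PatientID")
        test_clin.index = ["T" + pid for pid in test_clin.index]
        for p in test_patients:
            p.patient_id = "T" + p.patient_id
        clinical = pd.concat([clinical, test_clin])
        labels = clinical["STAS"].astype(int)
        split = pd.concat(
            [split, pd.Series("test", index=test_clin.index, name="split")]
        )
        patients = patients + test_patients
    else:
        log.warning("no external test cohort; models evaluated on train/validation only")

    train_idx = split.index[split == "train"]
    val_idx = split.index[split == "validation"]

    # habitat cluster count: cohort-wide mean CH on the training split
    if config.fixed_k is not None:
        k_star = int(config.fixed_k)
    else:
        fms = [
            local_feature_map(p.ct, p.tumor_mask)
            for p in patients
            if split.loc[p.patient_id] == "train"
        ]
        k_star = select_k(fms, config.k_grid, seed=rng_seed).k_star
    log.info("habitat cluster count k* = %d", k_star)

    cases, _ = build_regions(patients, config.ring_distances_mm, k=k_star, seed=rng_seed)
    # extract only the regions the configured models consume
    needed = tuple(p for r in config.regions for p in REGION_MODELS[r])
    cases = [
        (pid, ct, {t: m for t, m in regions.items() if (t + "_").startswith(needed)})
        for pid, ct, regions in cases
    ]
    table = extract_all(cases, DiscretizationSpec())
    table = knn_impute(table, train_idx)

    models: dict[str, object] = {}
    selection: dict[str, object] = {}
    reports: dict[str, dict] = {}
    predictions: dict[str, pd.DataFrame] = {}

    design = clinical_design(clinical)
    regression = ev.logistic_regression(design.loc[train_idx], labels.loc[train_idx])
    predictors = regression.independent_predictors or regression.significant
    if not predictors:
        # small-cohort fallback: strongest univariable association, logged
        best = regression.univariable["p"].idxmin()
        log.warning("no significant clinical variable; falling back to %s", best)
        predictors = [best]
    # normalize the clinical design with training statistics for scale-
    # sensitive families (KNN, MLP)
    from .feature_selection import zscore_fit_apply

    design_z, _ = zscore_fit_apply(design, train_idx)
    predictors = [p for p in predictors if p in design_z.columns]
    clin_model, clin_report = mz.train_clinical_model(
        design_z, labels, train_idx, val_idx, predictors,
        specs=mz.default_specs(rng_seed),
    )
    models["Clinical"] = clin_model
    reports["Clinical"] = {"algorithms": clin_report, "predictors": predictors}
    predictions["Clinical"] = mz.prediction_set(clin_model, design_z, labels, split)

    normalized_frames: list[pd.DataFrame] = [design_z]
    for region in config.regions:
        cols = region_columns(table, region)
        sub, report = run_cascade(
            table[cols], labels, train_idx,
            mrmr_m=config.mrmr_m, lasso_folds=config.lasso_folds, seed=rng_seed,
        )
        selection[region] = report
        if not report.final_features:
            log.warning("region %s: cascade selected no features; model skipped", region)
            continue
        model, algo_report = mz.train_region_model(
            sub, labels, train_idx, val_idx, region,
            specs=mz.default_specs(rng_seed),
        )
        models[region] = model
        reports[region] = {"algorithms": algo_report}
        predictions[region] = mz.prediction_set(model, sub, labels, split)
        normalized_frames.append(sub)

    # Combined = Habitat + Peri3mm + Clinical stack; bases must see the same
    # normalized feature frames they were trained on
    base_names = [r for r in ("Habitat", "Peri3mm", "Clinical") if r in models]
    joined = pd.concat(normalized_frames, axis=1)
    combined = mz.fuse_combined(
        [models[r] for r in base_names], joined, labels, train_idx, seed=rng_seed
    )
    models["Combined"] = combined
    predictions["Combined"] = mz.prediction_set(combined, joined, labels, split)

    evaluation = {name: ev.evaluate_model(preds) for name, preds in predictions.items()}
    for name in reports:
        reports[name]["evaluation"] = evaluation.get(name)
    reports.setdefault("Combined", {})["evaluation"] = evaluation["Combined"]

    result = RunResult(
        models=models,
        predictions=predictions,
        reports=reports,
        selection=selection,
        feature_table=table,
        labels=labels,
        split=split,
        k_star=k_star,
        regression=regression,
    )
    if config.output_dir is not None:
        _persist(result, config)
    return result


def _persist(result: RunResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.feature_table.to_csv(out / "features.csv")
    pd.concat(result.predictions.values()).to_csv(out / "predictions.csv")
    summary = {
        "seed": config.seed,
        "k_star": result.k_star,
        "models": {
            name: result.reports.get(name, {}).get("evaluation")
            for name in result.models
        },
    }
    (out / "evaluation.json").write_text(json.dumps(summary, indent=2, default=float))
    log.info("run artifacts written to %s", out)
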