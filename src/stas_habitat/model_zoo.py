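"""Classifier training, winner selection, and model fusion.

Five algorithm families are tuned per region model — logistic regression,
k-nearest neighbours, random forest, leaf-wise gradient-boosted trees
(LightGBM), and a multilayer perceptron — each by stratified 5-fold
cross-validation on the training split over a small fixed hyperparameter
grid.  The winning family for a region is the one with the highest
validation-split AUC (winner selection is the only step that sees validation
labels, and is logged as such).  The Combined model stacks the Habitat,
Peri3mm, and Clinical base models: out-of-fold base probabilities on the
training split feed an unpenalized logistic meta-learner.

The operating threshold for confusion metrics is Youden-optimal on the
training split and frozen for validation/test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

log = logging.getLogger(__name__)

ALGORITHMS = ("logistic", "knn", "random_forest", "lightgbm", "mlp")

# small fixed grids: reproducibility over exhaustiveness
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logistic": {"C": [0.1, 1.0]},
    "knn": {"n_neighbors": [5, 11]},
    "random_forest": {"n_estimators": [100], "max_depth": [6, None]},
    "lightgbm": {"n_estimators": [100, 300], "max_depth": [3, -1]},
    "mlp": {"hidden_layer_sizes": [(32,), (64, 32)], "alpha": [1e-2]},
}


@dataclass
class ModelSpec:
    algorithm: str
    grid: dict[str, list] = field(default_factory=dict)
    tuning_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.grid:
            self.grid = DEFAULT_GRIDS[self.algorithm]


def default_specs(seed: int = 0) -> list[ModelSpec]:
    return [ModelSpec(a, seed=seed) for a in ALGORITHMS]


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "logistic":
        return LogisticRegression(max_iter=2000, **params)
    if algorithm == "knn":
        return KNeighborsClassifier(**params)
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm == "lightgbm":
        return LGBMClassifier(
            random_state=seed, verbose=-1, num_leaves=15, min_child_samples=5, **params
        )
    if algorithm == "mlp":
        return MLPClassifier(max_iter=300, random_state=seed, **params)
    raise ValueError(algorithm)


@dataclass
class TrainedModel:
    """A fitted region model with its provenance."""

    estimator: object
    algorithm: str
    hyperparameters: dict
    cv_auc: float
    features: list[str]
    region: str
    threshold: float = 0.5
    validation_auc: float = float("nan")

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.features].to_numpy(dtype=np.float64)
        return self.estimator.predict_proba(X)[:, 1]


def _grid_points(grid: dict[str, list]):
    keys = list(grid)
    for combo in product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def _cv_folds(y: np.ndarray, folds: int, seed: int) -> StratifiedKFold:
    # degenerate single-class folds are avoided by shrinking the fold count
    smallest = min(int((y == 1).sum()), int((y == 0).sum()))
    if smallest < folds:
        log.warning("refolding: %d-fold CV infeasible, using %d folds", folds, smallest)
        folds = max(2, smallest)
    return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)


def _tune_one(
    X: np.ndarray, y: np.ndarray, spec: ModelSpec
) -> tuple[object, dict, float]:
    """Grid search by stratified CV mean AUC on the training split."""
    skf = _cv_folds(y, spec.tuning_folds, spec.seed)
    splits = list(skf.split(X, y))
    best_params, best_auc = None, -np.inf
    for params in _grid_points(spec.grid):
        aucs = []
        for tr, va in splits:
            est = _make_estimator(spec.algorithm, params, spec.seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X[tr], y[tr])
                prob = est.predict_proba(X[va])[:, 1]
            aucs.append(roc_auc_score(y[va], prob))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_params, best_auc = params, mean_auc
    final = _make_estimator(spec.algorithm, best_params, spec.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    return final, best_params, best_auc


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability cut maximizing sensitivity + specificity − 1."""
    fpr, tpr, thresholds = roc_curve(labels, scores)
    j = tpr - fpr
    t = float(thresholds[int(np.argmax(j))])
    return min(max(t, 0.0), 1.0)


def train_region_model(
    table: pd.DataFrame,
    labels: pd.Series,
    train_index,
    validation_index,
    region: str,
    specs: list[ModelSpec] | None = None,
    features: list[str] | None = None,
) -> tuple[TrainedModel, pd.DataFrame]:
    """Tune every algorithm family and pick the validation-AUC winner.

    Each family is tuned by stratified 5-fold CV on the training split; the
    winner is the family with the highest validation-split AUC (ties broken
    by the fixed algorithm order).  Returns the winning model (refitted on
    the training split, Youden threshold frozen there) and the per-algorithm
    report.
    """
    features = features if features is not None else list(table.columns)
    if not features:
        raise ValueError("empty feature set")
    specs = specs or default_specs()
    X_tr = table.loc[train_index, features].to_numpy(dtype=np.float64)
    y_tr = labels.loc[train_index].astype(int).to_numpy()
    X_va = table.loc[validation_index, features].to_numpy(dtype=np.float64)
    y_va = labels.loc[validation_index].astype(int).to_numpy()
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training split must contain both classes")

    rows = []
    candidates: dict[str, TrainedModel] = {}
    for spec in specs:
        est, params, cv_auc = _tune_one(X_tr, y_tr, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val_auc = float(roc_auc_score(y_va, est.predict_proba(X_va)[:, 1]))
        thr = youden_threshold(est.predict_proba(X_tr)[:, 1], y_tr)
        candidates[spec.algorithm] = TrainedModel(
            estimator=est,
            algorithm=spec.algorithm,
            hyperparameters=params,
            cv_auc=cv_auc,
            features=features,
            region=region,
            threshold=thr,
            validation_auc=val_auc,
        )
        rows.append(
            {"algorithm": spec.algorithm, "cv_auc": cv_auc, "validation_auc": val_auc,
             "hyperparameters": str(params)}
        )
    report = pd.DataFrame(rows)
    order = {a: i for i, a in enumerate(ALGORITHMS)}
    winner_name = max(
        candidates, key=lambda a: (candidates[a].validation_auc, -order[a])
    )
    log.info(
        "region %s: winner %s by validation AUC %.3f (validation labels used for "
        "winner selection only)", region, winner_name,
        candidates[winner_name].validation_auc,
    )
    return candidates[winner_name], report


def train_clinical_model(
    clinical_design: pd.DataFrame,
    labels: pd.Series,
    train_index,
    validation_index,
    predictors: list[str],
    specs: list[ModelSpec] | None = None,
) -> tuple[TrainedModel, pd.DataFrame]:
    """Clinical model on the multivariable-significant predictor set."""
    if not predictors:
        raise ValueError(
            "no clinical predictors; inspect the univariable/multivariable "
            "regression report before building the clinical model"
        )
    return train_region_model(
        clinical_design, labels, train_index, validation_index,
        region="Clinical", specs=specs, features=predictors,
    )


class _NonNegLogistic:
    """Logistic combiner with non-negative base weights.

    Stacked probability combiners are fitted on few, noisy, collinear
    out-of-fold columns; unconstrained fits routinely flip signs and can hand
    the ensemble to an anti-weighted base.  Constraining base weights to be
    non-negative (the classical remedy for stacked ensembles) removes that
    failure mode: a useless base gets weight ~0 and the stack degrades to its
    informative members.
    """

    def __init__(self, l2: float = 1.0):
        self.l2 = l2
        self.coef_ = None
        self.intercept_ = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_NonNegLogistic":
        from scipy.optimize import minimize
        from scipy.special import expit

        n, p = X.shape

        def nll(params):
            w, b = params[:p], params[p]
            eta = X @ w + b
            # log(1+e^eta) - y*eta, numerically stable
            loss = np.logaddexp(0.0, eta) - y * eta
            return loss.sum() / n + self.l2 * (w @ w) / (2 * n)

        res = minimize(
            nll, x0=np.zeros(p + 1), method="L-BFGS-B",
            bounds=[(0.0, None)] * p + [(None, None)],
        )
        self.coef_ = res.x[:p][None, :]
        self.intercept_ = res.x[p : p + 1]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        p1 = expit(X @ self.coef_.ravel() + self.intercept_[0])
        return np.column_stack([1.0 - p1, p1])


def _fit_nonneg_logistic(X: np.ndarray, y: np.ndarray) -> _NonNegLogistic:
    return _NonNegLogistic().fit(X, y)


def _embed_meta(meta: _NonNegLogistic, selected: list[int], n_bases: int) -> _NonNegLogistic:
    """Expand a combiner fitted on a base subset to the full base list
    (unselected bases get weight zero)."""
    full = _NonNegLogistic(l2=meta.l2)
    coef = np.zeros((1, n_bases))
    coef[0, selected] = meta.coef_.ravel()
    full.coef_ = coef
    full.intercept_ = meta.intercept_
    return full


@dataclass
class StackedModel:
    """Logistic stack over base-model probabilities."""

    base_models: list[TrainedModel]
    meta: object
    region: str = "Combined"
    threshold: float = 0.5
    features: list[str] = field(default_factory=list)

    @property
    def algorithm(self) -> str:
        return "stacking[" + "+".join(m.region for m in self.base_models) + "]"

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        base = np.column_stack([m.predict_proba(table) for m in self.base_models])
        return self.meta.predict_proba(base)[:, 1]


def fuse_combined(
    base_models: list[TrainedModel],
    table: pd.DataFrame,
    labels: pd.Series,
    train_index,
    folds: int = 5,
    seed: int = 0,
    repeats: int = 2,
) -> StackedModel:
    """Stack base models with an unpenalized logistic meta-learner.

    The meta-learner is fitted on out-of-fold base probabilities over the
    training split (each base estimator is refitted inside every fold at its
    chosen hyperparameters), so no meta-feature is an in-fold prediction —
    the stacking analogue of the leakage guard.
    """
    if not base_models:
        raise ValueError("no base models to fuse")
    y = labels.loc[train_index].astype(int).to_numpy()
    n = len(train_index)
    idx = pd.Index(train_index)
    # OOF probabilities averaged over repeated fold splits: a single 5-fold
    # assignment leaves noticeable fold-assignment noise in both the meta
    # weights and the admission decisions below
    oof = np.zeros((n, len(base_models)))
    for rep in range(max(1, repeats)):
        skf = _cv_folds(y, folds, seed + 101 * rep)
        for tr, va in skf.split(np.zeros(n), y):
            for j, base in enumerate(base_models):
                est = _make_estimator(base.algorithm, base.hyperparameters, seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(
                        table.loc[idx[tr], base.features].to_numpy(dtype=np.float64),
                        y[tr],
                    )
                    oof[va, j] += est.predict_proba(
                        table.loc[idx[va], base.features].to_numpy(dtype=np.float64)
                    )[:, 1]
    oof /= max(1, repeats)
    # forward ensemble selection on the out-of-fold design: start from the
    # best base and admit further bases only when they improve the
    # cross-validated AUC of the combiner over the OOF rows.  Without this, a
    # few dozen noisy OOF rows routinely hand nonzero weight to an unhelpful
    # base and the stack lands below its own best member; evaluating
    # admissions in-sample is not enough, since an extra column almost always
    # improves the fit it was trained on.
    inner = [
        fold
        for rep in range(max(1, repeats))
        for fold in _cv_folds(y, folds, seed + 1 + 101 * rep).split(oof, y)
    ]

    def cv_fold_aucs(cols: list[int]) -> np.ndarray:
        aucs = []
        for tr2, va2 in inner:
            m = _fit_nonneg_logistic(oof[np.ix_(tr2, cols)], y[tr2])
            prob = m.predict_proba(oof[np.ix_(va2, cols)])[:, 1]
            aucs.append(
                roc_auc_score(y[va2], prob) if len(np.unique(y[va2])) == 2 else 0.5
            )
        return np.asarray(aucs)

    singles = [cv_fold_aucs([j]) for j in range(oof.shape[1])]
    single_means = [float(a.mean()) for a in singles]
    selected = [int(np.argmax(single_means))]
    best_folds = singles[selected[0]]
    remaining = [j for j in range(oof.shape[1]) if j not in selected]
    while remaining:
        # admit the best candidate only when its fold-paired AUC improvement
        # exceeds one standard error (same 1-SE convention as the λ rule):
        # gains indistinguishable from CV noise do not enter the stack
        trials = {j: cv_fold_aucs(selected + [j]) for j in remaining}
        j_best = max(trials, key=lambda j: trials[j].mean())
        delta = trials[j_best] - best_folds
        se = delta.std(ddof=1) / np.sqrt(len(delta)) if len(delta) > 1 else np.inf
        if delta.mean() <= se:
            break
        selected.append(int(j_best))
        best_folds = trials[j_best]
        remaining.remove(j_best)
    meta = _fit_nonneg_logistic(oof[:, selected], y)
    log.info("stack admitted bases %s (single-base CV AUCs %s)",
             [base_models[j].region for j in selected], np.round(single_means, 3))
    meta = _embed_meta(meta, selected, oof.shape[1])
    stacked = StackedModel(base_models=list(base_models), meta=meta)
    stacked.threshold = youden_threshold(stacked.predict_proba(table.loc[idx]), y)
    return stacked


def prediction_set(
    model: TrainedModel | StackedModel,
    table: pd.DataFrame,
    labels: pd.Series,
    split: pd.Series,
) -> pd.DataFrame:
    """Per-patient probabilities, thresholded calls, labels, and split tags."""
    prob = model.predict_proba(table)
    return pd.DataFrame(
        {
            "probability": prob,
            "prediction": (prob >= model.threshold).astype(int),
            "label": labels.astype(int).to_numpy(),
            "split": split.to_numpy(),
            "model": getattr(model, "region", "model"),
        },
        index=table.index,
    )
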