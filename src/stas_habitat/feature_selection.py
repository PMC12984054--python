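"""The five-stage feature-selection cascade.

Stages, in order: ICC reproducibility filter (two-way random, absolute
agreement, ICC(2,1) > 0.75 for both inter- and intra-observer matrices) →
Z-score normalization (training statistics applied to all splits) →
Mann–Whitney U screening (two-sided, p < 0.05) → Pearson redundancy pruning
(|r| > 0.9, keep the feature with the smaller U-test p) → mRMR ranking
(greedy mutual-information difference criterion) → L1-penalized logistic
regression with 10-fold cross-validated λ.

Every fitted quantity — normalization statistics, test p-values, correlation
and MI estimates, the LASSO path — is computed on the training split only;
survivor sets are nested stage to stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, mutual_info_score
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)


@dataclass
class SelectionReport:
    """Per-stage survivors and diagnostics; survivors are nested."""

    stages: dict[str, list[str]] = field(default_factory=dict)
    icc_values: dict[str, float] = field(default_factory=dict)
    u_pvalues: dict[str, float] = field(default_factory=dict)
    pruned_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    mrmr_scores: dict[str, float] = field(default_factory=dict)
    lasso_lambda: float = float("nan")
    lasso_coefficients: dict[str, float] = field(default_factory=dict)
    lambda_grid: np.ndarray | None = None
    cv_deviance: np.ndarray | None = None

    def record(self, stage: str, survivors: list[str]) -> None:
        for prev in reversed(list(self.stages.values())):
            missing = set(survivors) - set(prev)
            if missing:
                raise ValueError(f"stage {stage} is not nested: {sorted(missing)[:3]}")
            break
        self.stages[stage] = list(survivors)

    @property
    def final_features(self) -> list[str]:
        return list(self.stages[next(reversed(self.stages))]) if self.stages else []


# ---------------------------------------------------------------------------
# ICC


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is (n_cases, n_raters).  Computed from the classical ANOVA
    mean squares: (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n).
    """
    ratings = np.asarray(ratings, dtype=np.float64)
    n, k = ratings.shape
    if n < 5 or k < 2:
        raise ValueError("ICC needs ≥ 5 cases and ≥ 2 raters/sessions")
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((ratings - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ZeroDivisionError("zero between-case variance; ICC undefined")
    return float((msr - mse) / denom)


def icc_filter(
    ratings: dict[str, np.ndarray] | list[dict[str, np.ndarray]],
    threshold: float = 0.75,
) -> tuple[list[str], dict[str, float]]:
    """Keep features whose ICC(2,1) exceeds the threshold in every matrix.

    ``ratings`` maps feature name -> (cases × raters/sessions) matrix, or is a
    list of such maps (e.g. one inter-observer and one intra-observer study);
    a feature must clear the threshold in all of them.  Features with
    undefined ICC (no between-case variance) are dropped with a warning.
    """
    if isinstance(ratings, dict):
        ratings = [ratings]
    names = list(ratings[0])
    values: dict[str, float] = {}
    survivors = []
    for name in names:
        iccs = []
        try:
            for mat in ratings:
                iccs.append(icc_2_1(mat[name]))
        except ZeroDivisionError:
            log.warning("feature %s: ICC undefined (no between-case variance); dropped", name)
            continue
        values[name] = min(iccs)
        if values[name] > threshold:
            survivors.append(name)
    return survivors, values


# ---------------------------------------------------------------------------
# normalization and univariate screening


def zscore_fit_apply(
    table: pd.DataFrame, train_index
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score every column with training-split mean/SD (population SD).

    Returns (normalized table, scaler frame with ``mean``/``sd`` rows).
    Zero-SD training columns are dropped with a warning, never divided.
    """
    train = table.loc[train_index]
    if train.empty:
        raise ValueError("empty training split")
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    constant = sd.index[sd == 0]
    if len(constant):
        log.warning("dropping %d constant training column(s)", len(constant))
    keep = sd.index[sd > 0]
    out = (table[keep] - mu[keep]) / sd[keep]
    scaler = pd.DataFrame({"mean": mu[keep], "sd": sd[keep]}).T
    return out, scaler


def mannwhitney_filter(
    table: pd.DataFrame,
    labels: pd.Series,
    train_index,
    alpha: float = 0.05,
) -> tuple[list[str], dict[str, float]]:
    """Two-sided Mann–Whitney U screen on the training split; keep p < alpha."""
    y = labels.loc[train_index].astype(int)
    X = table.loc[train_index]
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("each class needs ≥ 2 training members")
    pvals: dict[str, float] = {}
    survivors = []
    pos, neg = X[y == 1], X[y == 0]
    for col in table.columns:
        if X[col].nunique() < 2:  # all ties: no evidence against the null
            pvals[col] = 1.0
            continue
        _, p = stats.mannwhitneyu(pos[col], neg[col], alternative="two-sided")
        pvals[col] = float(p)
        if p < alpha:
            survivors.append(col)
    return survivors, pvals


def pearson_prune(
    table: pd.DataFrame,
    u_pvalues: dict[str, float],
    train_index,
    r_threshold: float = 0.9,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy redundancy pruning on training rows.

    Pairs with |r| > threshold are visited in descending |r|; the member with
    the larger U-test p-value is dropped (tie: the lexicographically later
    name).  No surviving pair exceeds the threshold.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        return cols, []
    corr = table.loc[train_index, cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    order = np.argsort(corr, axis=None)[::-1]
    dropped: set[str] = set()
    pruned: list[tuple[str, str, float]] = []
    for flat in order:
        i, j = divmod(flat, len(cols))
        r = corr[i, j]
        if r <= r_threshold:
            break
        if i > j:
            continue  # visit each unordered pair once
        a, b = cols[i], cols[j]
        if a in dropped or b in dropped:
            continue
        pa, pb = u_pvalues.get(a, 1.0), u_pvalues.get(b, 1.0)
        if pa < pb:
            loser = b
        elif pb < pa:
            loser = a
        else:
            loser = max(a, b)
        dropped.add(loser)
        pruned.append((a, b, float(r)))
    return [c for c in cols if c not in dropped], pruned


# ---------------------------------------------------------------------------
# mRMR


def _equal_frequency_bins(x: np.ndarray, bins: int = 4) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.digitize(x, edges)


def mrmr_select(
    table: pd.DataFrame,
    labels: pd.Series,
    train_index,
    m: int = 30,
    bins: int = 4,
) -> tuple[list[str], dict[str, float]]:
    """Greedy mRMR ranking with the MID (difference) criterion.

    Relevance and redundancy are plug-in mutual information after
    equal-frequency discretization into ``bins`` levels; the first pick
    maximizes I(f; y), each next pick maximizes I(f; y) − mean I(f; s) over
    the already-selected set.  Deterministic given the table.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    cols = list(table.columns)
    m = min(m, len(cols))
    y = labels.loc[train_index].astype(int).to_numpy()
    disc = {c: _equal_frequency_bins(table.loc[train_index, c].to_numpy(), bins) for c in cols}
    relevance = {c: mutual_info_score(y, disc[c]) for c in cols}
    pairwise: dict[tuple[str, str], float] = {}

    def redundancy(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in pairwise:
            pairwise[key] = mutual_info_score(disc[a], disc[b])
        return pairwise[key]

    selected: list[str] = []
    scores: dict[str, float] = {}
    remaining = set(cols)
    while len(selected) < m and remaining:
        best, best_score = None, -np.inf
        for c in sorted(remaining):  # sorted => deterministic tie-break
            red = np.mean([redundancy(c, s) for s in selected]) if selected else 0.0
            score = relevance[c] - red
            if score > best_score:
                best, best_score = c, score
        selected.append(best)
        scores[best] = float(best_score)
        remaining.discard(best)
    return selected, scores


# ---------------------------------------------------------------------------
# LASSO


def lasso_select(
    table: pd.DataFrame,
    labels: pd.Series,
    train_index,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    rule: str = "min",
) -> tuple[list[str], dict[str, float], float, np.ndarray, np.ndarray]:
    """L1-penalized logistic regression with CV-selected λ.

    λ* minimizes the mean cross-validated binomial deviance over a log-spaced
    grid (stratified folds, fixed seed); ``rule="1se"`` instead takes the
    largest λ within one standard error of the minimum (sparser, the glmnet
    parsimony convention).  Final features are the nonzero coefficients at
    λ*; if that λ zeroes everything, the largest λ with ≥ 1 nonzero
    coefficient is used instead (logged).

    Returns (features, coefficients, λ*, λ grid, CV deviance per λ).
    """
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    X = table.loc[train_index].to_numpy(dtype=np.float64)
    y = labels.loc[train_index].astype(int).to_numpy()
    n, p = X.shape
    folds = min(folds, int((y == 1).sum()), int((y == 0).sum()))
    if folds < 2:
        raise ValueError("too few members of a class for cross-validation")

    # largest λ that admits any nonzero coefficient (KKT bound), then 3 decades
    lam_max = np.abs(X.T @ (y - y.mean())).max() / n
    lam_grid = np.logspace(np.log10(lam_max * 1.05), np.log10(lam_max * 1e-3), n_lambdas)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_dev = []
    for tr, va in skf.split(X, y):
        row = np.empty(n_lambdas)
        for i, lam in enumerate(lam_grid):
            model = LogisticRegression(
                penalty="l1", C=1.0 / (lam * len(tr)), solver="liblinear",
                max_iter=1000, tol=1e-6, random_state=0,
            )
            model.fit(X[tr], y[tr])
            prob = model.predict_proba(X[va])[:, 1]
            row[i] = 2.0 * log_loss(y[va], prob, labels=[0, 1], normalize=False) / len(va)
        fold_dev.append(row)
    fold_dev = np.asarray(fold_dev)
    deviance = fold_dev.mean(axis=0)

    best = int(np.argmin(deviance))
    if rule == "1se":
        se = fold_dev[:, best].std(ddof=1) / np.sqrt(fold_dev.shape[0])
        within = np.where(deviance <= deviance[best] + se)[0]
        best = int(within[0])  # grid is descending in λ
    lam_star = float(lam_grid[best])

    def fit_at(lam: float) -> np.ndarray:
        model = LogisticRegression(
            penalty="l1", C=1.0 / (lam * n), solver="liblinear", max_iter=2000,
            tol=1e-6, random_state=0,
        )
        model.fit(X, y)
        return model.coef_.ravel()

    coef = fit_at(lam_star)
    if not np.any(coef != 0):
        log.warning("all coefficients zero at min-deviance λ; falling back to the knee")
        for lam in lam_grid:  # descending λ: first with any support
            coef = fit_at(float(lam))
            if np.any(coef != 0):
                lam_star = float(lam)
                break
    features = [c for c, w in zip(table.columns, coef) if w != 0]
    coefficients = {c: float(w) for c, w in zip(table.columns, coef) if w != 0}
    return features, coefficients, lam_star, lam_grid, deviance


# ---------------------------------------------------------------------------
# the cascade


def run_cascade(
    table: pd.DataFrame,
    labels: pd.Series,
    train_index,
    icc_ratings: dict[str, np.ndarray] | list[dict[str, np.ndarray]] | None = None,
    icc_threshold: float = 0.75,
    alpha: float = 0.05,
    r_threshold: float = 0.9,
    mrmr_m: int = 30,
    lasso_folds: int = 10,
    lasso_rule: str = "min",
    seed: int = 0,
) -> tuple[pd.DataFrame, SelectionReport]:
    """ICC → Z-score → U test → Pearson prune → mRMR → LASSO.

    Returns the normalized table restricted to the final features (all rows)
    and the full :class:`SelectionReport`.  The ICC stage is skipped when no
    repeat-rating study is supplied.
    """
    report = SelectionReport()
    report.record("input", list(table.columns))

    cols = list(table.columns)
    if icc_ratings is not None:
        cols, report.icc_values = icc_filter(icc_ratings, icc_threshold)
        cols = [c for c in table.columns if c in set(cols)]
    report.record("icc", cols)

    normalized, _ = zscore_fit_apply(table[cols], train_index)
    report.record("zscore", list(normalized.columns))

    survivors, report.u_pvalues = mannwhitney_filter(normalized, labels, train_index, alpha)
    report.record("mannwhitney", survivors)
    if not survivors:
        return normalized[[]], report

    survivors, report.pruned_pairs = pearson_prune(
        normalized[survivors], report.u_pvalues, train_index, r_threshold
    )
    report.record("pearson", survivors)

    survivors, report.mrmr_scores = mrmr_select(
        normalized[survivors], labels, train_index, mrmr_m
    )
    report.record("mrmr", survivors)

    final, coefs, lam, grid, dev = lasso_select(
        normalized[survivors], labels, train_index, lasso_folds, seed, rule=lasso_rule
    )
    report.record("lasso", final)
    report.lasso_coefficients = coefs
    report.lasso_lambda = lam
    report.lambda_grid = grid
    report.cv_deviance = dev
    return normalized[final], report
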