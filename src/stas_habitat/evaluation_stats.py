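"""Inferential statistics for model evaluation and clinical tables.

ROC AUC with DeLong variance and the paired DeLong test, confusion metrics at
a frozen threshold, Hosmer–Lemeshow calibration, decision-curve net benefit,
2×2 odds ratios with Wald CIs, univariable/multivariable logistic regression
(Wald ORs via maximum likelihood), and Cohen's kappa.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

UNDEFINED = float("nan")  #: sentinel for metrics with a zero denominator


# ---------------------------------------------------------------------------
# DeLong AUC


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


@dataclass
class AucResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def auc_delong(scores, labels) -> AucResult:
    """Mann–Whitney AUC (ties count 0.5) with DeLong variance and normal CI.

    The CI is AUC ± 1.96·SE truncated to [0, 1]; perfectly separated scores
    give zero variance and a degenerate CI.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = v10.size, v01.size
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = np.sqrt(var)
    return AucResult(
        auc=float(auc),
        variance=float(var),
        ci_low=float(max(0.0, auc - 1.96 * se)),
        ci_high=float(min(1.0, auc + 1.96 * se)),
    )


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided paired DeLong test for correlated AUCs; returns (z, p)."""
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 0:
        if auc_a != auc_b:
            warnings.warn("non-positive variance of AUC difference; returning p = 1")
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# threshold metrics, calibration, decision curves


def confusion_metrics(scores, labels, threshold: float) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV, NPV at a probability cut.

    Zero-denominator predictive values are reported as NaN sentinels.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    total = tp + fp + fn + tn

    def ratio(num, den):
        return num / den if den > 0 else UNDEFINED

    return {
        "accuracy": ratio(tp + tn, total),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def hosmer_lemeshow(
    probabilities, labels, bins: int = 10, fitted: bool = True
) -> tuple[float, float]:
    """Hosmer–Lemeshow goodness-of-fit over deciles of predicted risk.

    χ² = Σ_g (O_g − E_g)² / (E_g(1 − E_g/n_g)).  With ``fitted=True`` (the
    classic test for probabilities estimated on the same data) p comes from
    χ²(bins − 2); with ``fitted=False`` (externally given or true
    probabilities, e.g. held-out predictions or a simulation null) the
    statistic is referred to χ²(bins), the correct null reference when no
    parameters were estimated.  Bins emptied by tied probabilities are
    merged into their neighbour (logged).
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if p.size < bins:
        raise ValueError("need at least one observation per bin")
    edges = np.quantile(p, np.linspace(0, 1, bins + 1)[1:-1])
    group = np.digitize(p, edges)

    chi2 = 0.0
    used = 0
    for g in np.unique(group):
        sel = group == g
        n_g = int(sel.sum())
        if n_g == 0:
            continue
        obs = float(y[sel].sum())
        exp = float(p[sel].sum())
        denom = exp * (1.0 - exp / n_g)
        if denom <= 0:
            log.info("HL bin %d degenerate (expected %.3f); merged", g, exp)
            continue
        chi2 += (obs - exp) ** 2 / denom
        used += 1
    df = max(used - (2 if fitted else 0), 1)
    return float(chi2), float(stats.chi2.sf(chi2, df))


def decision_curve(
    scores, labels, thresholds: np.ndarray | None = None
) -> pd.DataFrame:
    """Net benefit NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t) over a threshold grid,
    with treat-all and treat-none references."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.linspace(0.0, 0.99, 100)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.min() < 0 or thresholds.max() >= 1:
        raise ValueError("thresholds must lie in [0, 1)")
    n = labels.size
    prevalence = labels.mean()
    rows = []
    for t in thresholds:
        w = t / (1.0 - t)
        pred = scores >= t if t > 0 else np.ones(n, dtype=bool)
        tp = float((pred & (labels == 1)).sum()) / n
        fp = float((pred & (labels == 0)).sum()) / n
        nb_all = prevalence - (1.0 - prevalence) * w
        rows.append(
            {"threshold": t, "net_benefit": tp - fp * w, "treat_all": nb_all, "treat_none": 0.0}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contingency tables and logistic regression


@dataclass
class ContingencyTable2x2:
    """Counts (a, b, c, d) = (exposed case, exposed control, unexposed case,
    unexposed control)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0 or self.total == 0:
            raise ValueError("counts must be non-negative with a positive total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool = False


def odds_ratio_wald(t: ContingencyTable2x2) -> OddsRatioResult:
    """OR = ad/(bc) with the Wald CI exp(ln OR ± 1.96·√(Σ 1/count)).

    A zero cell triggers the Haldane–Anscombe 0.5 correction (logged); a zero
    row or column leaves the OR undefined (NaN sentinel).
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return OddsRatioResult(UNDEFINED, UNDEFINED, UNDEFINED)
    corrected = False
    if min(a, b, c, d) == 0:
        log.info("zero cell; applying Haldane–Anscombe 0.5 correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)  # 1.959964…, the quantile standard software uses
    return OddsRatioResult(
        odds_ratio=float(or_),
        ci_low=float(np.exp(np.log(or_) - z * se)),
        ci_high=float(np.exp(np.log(or_) + z * se)),
        corrected=corrected,
    )


@dataclass
class RegressionReport:
    """Univariable and multivariable Wald OR tables."""

    univariable: pd.DataFrame
    multivariable: pd.DataFrame
    significant: list[str] = field(default_factory=list)
    independent_predictors: list[str] = field(default_factory=list)


def _logit_fit(X: pd.DataFrame, y: np.ndarray):
    """ML logistic fit; Firth-style (L2-regularized) fallback on separation."""
    design = sm.add_constant(X.astype(float), has_constant="add")
    model = sm.Logit(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True) or np.any(
                np.abs(res.params) > 50
            ):
                raise np.linalg.LinAlgError("suspect separation")
            return res
        except Exception:
            log.warning("separation or non-convergence; penalized fallback fit")
            return model.fit_regularized(disp=0, alpha=1e-3, L1_wt=0.0, maxiter=500)


def _wald_rows(res, columns) -> pd.DataFrame:
    params = pd.Series(res.params, index=res.model.exog_names)
    try:
        bse = pd.Series(res.bse, index=res.model.exog_names)
    except Exception:  # regularized results lack bse
        bse = pd.Series(np.nan, index=res.model.exog_names)
    rows = []
    for name in columns:
        beta, se = params[name], bse[name]
        p = 2 * stats.norm.sf(abs(beta / se)) if se and np.isfinite(se) and se > 0 else np.nan
        rows.append(
            {
                "variable": name,
                "or": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.96 * se)) if np.isfinite(se) else np.nan,
                "ci_high": float(np.exp(beta + 1.96 * se)) if np.isfinite(se) else np.nan,
                "p": float(p) if np.isfinite(p) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def logistic_regression(
    design: pd.DataFrame, labels, alpha: float = 0.05
) -> RegressionReport:
    """Univariable screens followed by a multivariable fit.

    Each column is fitted alone against the label; columns with univariable
    Wald p < alpha enter the multivariable model together.  Independent
    predictors are multivariable p < alpha.
    """
    y = np.asarray(labels).astype(int)
    uni_rows = []
    for col in design.columns:
        if design[col].nunique() < 2:
            log.warning("variable %s is constant; skipped", col)
            uni_rows.append(
                pd.DataFrame(
                    [{"variable": col, "or": np.nan, "ci_low": np.nan,
                      "ci_high": np.nan, "p": np.nan}]
                ).set_index("variable")
            )
            continue
        try:
            res = _logit_fit(design[[col]], y)
            uni_rows.append(_wald_rows(res, [col]))
        except np.linalg.LinAlgError:
            log.warning("variable %s: singular fit; skipped", col)
            uni_rows.append(
                pd.DataFrame(
                    [{"variable": col, "or": np.nan, "ci_low": np.nan,
                      "ci_high": np.nan, "p": np.nan}]
                ).set_index("variable")
            )
    univariable = pd.concat(uni_rows)
    significant = [c for c in design.columns if univariable.loc[c, "p"] < alpha]

    if significant:
        res = _logit_fit(design[significant], y)
        multivariable = _wald_rows(res, significant)
        independent = [c for c in significant if multivariable.loc[c, "p"] < alpha]
    else:
        multivariable = univariable.iloc[0:0]
        independent = []
    return RegressionReport(
        univariable=univariable,
        multivariable=multivariable,
        significant=significant,
        independent_predictors=independent,
    )


def cohens_kappa(ratings_a, ratings_b) -> float:
    """Chance-corrected agreement κ = (p_o − p_e)/(1 − p_e)."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape:
        raise ValueError("rating vectors must be paired")
    categories = np.union1d(a, b)
    po = float((a == b).mean())
    pe = sum(float((a == c).mean()) * float((b == c).mean()) for c in categories)
    if pe == 1.0:
        return UNDEFINED
    return (po - pe) / (1.0 - pe)


# ---------------------------------------------------------------------------
# model-level report


def evaluate_model(
    predictions: pd.DataFrame, hl_bins: int = 10
) -> dict[str, dict[str, float]]:
    """Full metric battery per split for one model's prediction set.

    ``predictions`` needs columns probability/prediction/label/split (see
    :func:`stas_habitat.model_zoo.prediction_set`).
    """
    out: dict[str, dict[str, float]] = {}
    for split, grp in predictions.groupby("split", sort=False):
        scores = grp["probability"].to_numpy()
        labels = grp["label"].to_numpy()
        auc = auc_delong(scores, labels)
        metrics = {
            "auc": auc.auc,
            "auc_ci_low": auc.ci_low,
            "auc_ci_high": auc.ci_high,
            "n": int(len(grp)),
        }
        thr_pred = grp["prediction"].to_numpy()
        tp = int(((thr_pred == 1) & (labels == 1)).sum())
        fp = int(((thr_pred == 1) & (labels == 0)).sum())
        fn = int(((thr_pred == 0) & (labels == 1)).sum())
        tn = int(((thr_pred == 0) & (labels == 0)).sum())

        def ratio(num, den):
            return num / den if den > 0 else UNDEFINED

        metrics.update(
            accuracy=ratio(tp + tn, len(grp)),
            sensitivity=ratio(tp, tp + fn),
            specificity=ratio(tn, tn + fp),
            ppv=ratio(tp, tp + fp),
            npv=ratio(tn, tn + fn),
        )
        if len(grp) >= hl_bins:
            chi2, p = hosmer_lemeshow(scores, labels, hl_bins)
            metrics.update(hl_chi2=chi2, hl_p=p)
        out[str(split)] = metrics
    return out
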