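"""Feature selection, ROC analysis, and the combined logistic model.

The inferential spine of the workflow:

1. *Univariate filter* — every candidate texture feature is compared between
   the CR and non-CR groups with a two-sided Mann-Whitney U test; features
   with p >= alpha (default 0.05) are eliminated.
2. *Per-category selection* — surviving features are grouped into four
   categories (FDG uptake intensity, grey-level distribution, tumor size,
   intratumor heterogeneity) and the lowest-p survivor per category is kept.
   Exact p-value ties are broken in favor of the percentile/rank-type
   feature when normality is rejected for the tied features, otherwise
   toward the moment-type feature.
3. *ROC analysis* — empirical ROC with trapezoid AUC (identical to the
   tie-corrected U/(n1 n2) rank statistic), auto-oriented so AUC >= 0.5,
   cutoff by Youden J maximization (ties toward higher sensitivity), calls
   strictly beyond the cutoff. Positive class: non-CR.
4. *DeLong comparison* of two correlated AUCs via placement values.
5. *Combined model* — unpenalized maximum-likelihood logistic regression
   (Newton-Raphson) of non-CR on SUVmax, first-order entropy, ROI volume
   and intestinal involvement; its fitted probability is the "prediction
   probability" scored by ROC, with Hosmer-Lemeshow deciles-of-risk
   calibration (df = groups - 2).

SUVmax and MTV bypass the texture filter and are always reported in the ROC
table; MTV is excluded from the tumor-size category (the manual-ROI volume
is that category's candidate). Evaluation is in-sample by design.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pettex.stats_core import (
    TestResult,
    chi2_upper_tail,
    mann_whitney_u,
    normal_two_sided_p,
)

__all__ = [
    "CATEGORIES",
    "default_category_map",
    "univariate_filter",
    "select_per_category",
    "RocResult",
    "roc_analysis",
    "delong_compare",
    "LogisticModel",
    "fit_prediction_probability",
    "hosmer_lemeshow",
]

CATEGORIES = ("uptake_intensity", "intensity_distribution", "tumor_size", "heterogeneity")

#: features whose value is a grey-level rank/percentile rather than a moment;
#: used by the tie-break rule under non-normality
RANK_TYPE_FEATURES = frozenset(
    {"p5", "p10", "p25", "p50", "p75", "p90", "minimum", "maximum", "mode"}
)


def default_category_map(feature_names: Sequence[str]) -> dict[str, str]:
    """Assign each candidate feature to one of the four selection categories.

    PET grey-level location features (mean, mode, min/max, percentiles)
    describe FDG uptake intensity; spread/shape features (SD, max-frequency,
    skewness, kurtosis) and all CT first-order intensity features describe
    the grey-level distribution; volumes and diameters describe tumor size;
    first-order entropy and every GLCM feature describe intratumor
    heterogeneity. SUVmax and MTV are excluded (reported separately, outside
    the texture filter).
    """
    mapping: dict[str, str] = {}
    for name in feature_names:
        if name in ("suvmax", "mtv_mm3"):
            mapping[name] = "excluded"
        elif name in ("volume_mm3", "max_diameter_mm", "ct_max_diameter_mm"):
            mapping[name] = "tumor_size"
        elif name == "entropy" or "glcm" in name or name == "ct_entropy":
            mapping[name] = "heterogeneity"
        elif name in ("sd", "max_frequency", "skewness", "kurtosis") or name.startswith("ct_"):
            mapping[name] = "intensity_distribution"
        else:  # PET grey-level location features
            mapping[name] = "uptake_intensity"
    return mapping


def univariate_filter(
    features: pd.DataFrame,
    labels: Sequence[str],
    alpha: float = 0.05,
    positive_label: str = "nonCR",
) -> tuple[list[str], pd.DataFrame]:
    """Eliminate features without a significant two-group rank difference.

    Returns the surviving feature names and the full per-feature p-value
    table (kept for reporting). Constant columns get p = 1 and a warning
    flag.
    """
    labels = np.asarray(labels)
    pos = labels == positive_label
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValueError("need >= 2 patients per class")
    rows = {}
    for name in features.columns:
        col = features[name].to_numpy(dtype=np.float64)
        if np.ptp(col) == 0:
            rows[name] = {"p_value": 1.0, "warning": "constant feature"}
            continue
        res = mann_whitney_u(col[pos], col[~pos], sidedness="two")
        rows[name] = {"p_value": res.p_value, "warning": None}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["retained"] = table["p_value"] < alpha
    survivors = [n for n in features.columns if table.loc[n, "retained"]]
    return survivors, table


def select_per_category(
    p_values: Mapping[str, float],
    categories: Mapping[str, str],
    normality_p: Mapping[str, float] | None = None,
    alpha_normality: float = 0.05,
) -> dict[str, str]:
    """Pick the lowest-p survivor in each category.

    ``p_values`` holds the filter p-values of the *surviving* features only.
    Exact ties are broken in favor of the rank/percentile-type feature when
    normality is rejected for any tied feature, otherwise toward the
    moment-type feature; remaining ties fall back to name order. Categories
    with no survivor are skipped.
    """
    normality_p = normality_p or {}
    selected: dict[str, str] = {}
    for cat in CATEGORIES:
        members = [f for f in p_values if categories.get(f) == cat]
        if not members:
            continue
        best_p = min(p_values[f] for f in members)
        tied = sorted(f for f in members if abs(p_values[f] - best_p) < 1e-12)
        if len(tied) == 1:
            selected[cat] = tied[0]
            continue
        non_normal = any(normality_p.get(f, 1.0) < alpha_normality for f in tied)
        prefer_rank = non_normal
        preferred = [
            f for f in tied if (_is_rank_type(f) if prefer_rank else not _is_rank_type(f))
        ]
        selected[cat] = (preferred or tied)[0]
    return selected


def _is_rank_type(name: str) -> bool:
    return name.removeprefix("ct_") in RANK_TYPE_FEATURES


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RocResult:
    """Empirical ROC summary for one marker (positive class: non-CR)."""

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    direction: str  # "higher-is-positive" or "lower-is-positive"
    p_value: float  # two-sided p for AUC != 0.5 (normal approx. on U)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _auc_rank(values: np.ndarray, positive: np.ndarray) -> float:
    """Tie-corrected AUC = U/(n1 n2) via mid-ranks."""
    from scipy.stats import rankdata

    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    ranks = rankdata(values, method="average")
    u = float(ranks[positive].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc_analysis(
    values: Sequence[float],
    labels: Sequence[str],
    positive_label: str = "nonCR",
) -> RocResult:
    """ROC with Youden-J cutoff for one marker.

    The orientation is chosen so AUC >= 0.5. A case is called positive when
    its value is strictly greater than the cutoff (strictly lower for
    lower-is-positive markers). Cutoff ties on Youden J are broken toward
    higher sensitivity.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    positive = labels == positive_label
    n_pos, n_neg = int(positive.sum()), int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")

    auc_raw = _auc_rank(values, positive)
    if auc_raw >= 0.5:
        direction, auc, oriented = "higher-is-positive", auc_raw, values
    else:
        direction, auc, oriented = "lower-is-positive", 1.0 - auc_raw, -values

    # candidate cutoffs: every observed value (strict > rule means the
    # highest value yields sensitivity 0, the value below the minimum is
    # represented by -inf giving sensitivity 1)
    cands = np.unique(oriented)
    cands = np.concatenate([[-np.inf], cands])
    best = None
    for c in cands:
        calls = oriented > c
        tp = int((calls & positive).sum())
        tn = int((~calls & ~positive).sum())
        sens = tp / n_pos
        spec = tn / n_neg
        j = sens + spec - 1.0
        key = (j, sens)
        if best is None or key > best[0]:
            best = (key, c, sens, spec, (tp + tn) / (n_pos + n_neg))
    _, cutoff, sens, spec, acc = best
    cutoff_out = float(cutoff) if np.isfinite(cutoff) else float(oriented.min() - 1.0)
    if direction == "lower-is-positive":
        cutoff_out = -cutoff_out

    # p-value for AUC != 0.5 through the rank-sum equivalence
    mw = mann_whitney_u(values[positive], values[~positive], sidedness="two")
    return RocResult(float(auc), cutoff_out, float(sens), float(spec), float(acc),
                     direction, mw.p_value)


def delong_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    labels: Sequence[str],
    positive_label: str = "nonCR",
) -> TestResult:
    """DeLong test for two correlated AUCs measured on the same patients.

    Placement-value covariance estimate; Z = (AUC_a - AUC_b) / SE with a
    two-sided normal p. Identical (or perfectly rank-correlated) markers
    have zero variance of the difference and return Z = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    labels = np.asarray(labels)
    if a.size != b.size or a.size != labels.size:
        raise ValueError("both markers must be measured on the same patients")
    positive = labels == positive_label
    m, n = int(positive.sum()), int((~positive).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    def placements(v):
        pos, neg = v[positive], v[~positive]
        # V10[i] = P(marker ranks a random negative below positive i)
        v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
        v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
        return v10, v01, v10.mean()

    v10a, v01a, auc_a = placements(a)
    v10b, v01b, auc_b = placements(b)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 1e-16:
        return TestResult("delong", 0.0, 1.0, "two", n=m + n,
                          warning="zero variance of the AUC difference")
    z = (auc_a - auc_b) / np.sqrt(var)
    return TestResult("delong", float(z), normal_two_sided_p(z), "two", n=m + n)


# ---------------------------------------------------------------------------
# logistic prediction probability
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class LogisticModel:
    """Unpenalized binary logistic fit and its per-patient probabilities."""

    predictors: list[str]
    coefficients: np.ndarray  # aligned with predictors
    intercept: float
    probabilities: np.ndarray  # fitted P(nonCR) per patient
    converged: bool
    log_likelihood: float
    n_iter: int
    warning: str | None = None


def fit_prediction_probability(
    features: pd.DataFrame,
    labels: Sequence[str],
    predictors: Sequence[str] = ("suvmax", "entropy", "volume_mm3", "intestinal_involvement"),
    positive_label: str = "nonCR",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticModel:
    """Maximum-likelihood logistic regression of non-CR on the combined panel.

    Newton-Raphson with an intercept; converged when the relative change in
    log-likelihood drops below ``tol``. Under perfect separation the fit is
    flagged non-converged and the last iterate's probabilities are returned
    with a warning.
    """
    predictors = list(predictors)
    missing = [p for p in predictors if p not in features.columns]
    if missing:
        raise ValueError(f"missing predictors: {missing}")
    X = features[predictors].to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("predictors contain missing values")
    y = (np.asarray(labels) == positive_label).astype(np.float64)
    n = y.size
    if n < 10:
        raise ValueError(f"need >= 10 patients; got {n}")

    # standardize internally for numerical stability; coefficients are
    # mapped back to the original units afterwards
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = np.column_stack([np.ones(n), (X - mu) / sd])
    beta = np.zeros(Xs.shape[1])
    ll_old = -np.inf
    converged = False
    warning = None
    for it in range(1, max_iter + 1):
        eta = Xs @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll = float(y @ np.log(p) + (1 - y) @ np.log(1 - p))
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll_old) + tol):
            converged = True
            break
        ll_old = ll
        W = p * (1 - p)
        H = Xs.T @ (Xs * W[:, None])
        grad = Xs.T @ (y - p)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(H.shape[0]), grad)
        except np.linalg.LinAlgError:
            warning = "singular Hessian (possible perfect separation)"
            break
        if np.max(np.abs(step)) > 50:  # runaway coefficients: separation
            warning = "perfect or quasi-perfect separation detected"
            beta = beta + step / np.max(np.abs(step)) * 50
            break
        beta = beta + step
    if warning is None and np.max(np.abs(beta[1:])) > 15:
        # log-odds of e^15 per standardized unit: (quasi-)separation
        warning = "perfect or quasi-perfect separation detected"
        converged = False
    eta = Xs @ beta
    probs = 1.0 / (1.0 + np.exp(-eta))
    coef_std = beta[1:]
    coefs = coef_std / sd
    intercept = float(beta[0] - np.sum(coef_std * mu / sd))
    ll = float(y @ np.log(np.clip(probs, 1e-12, 1)) + (1 - y) @ np.log(np.clip(1 - probs, 1e-12, 1)))
    return LogisticModel(
        predictors=predictors,
        coefficients=coefs,
        intercept=intercept,
        probabilities=probs,
        converged=converged and warning is None,
        log_likelihood=ll,
        n_iter=it,
        warning=warning,
    )


def hosmer_lemeshow(
    probabilities: Sequence[float],
    labels: Sequence[str],
    n_groups: int = 10,
    positive_label: str = "nonCR",
) -> TestResult:
    """Hosmer-Lemeshow deciles-of-risk calibration test.

    Subjects are grouped by quantiles of predicted probability; the
    chi-square sums (O - E)^2 / E over both outcomes in each group, with
    df = n_groups - 2. Groups with zero expected count are merged with
    their neighbor (warned).
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = (np.asarray(labels) == positive_label).astype(np.float64)
    if n_groups < 3:
        raise ValueError("need at least 3 groups")
    if p.size != y.size:
        raise ValueError("probabilities and labels must align")
    order = np.argsort(p, kind="mergesort")
    p, y = p[order], y[order]
    edges = np.linspace(0, p.size, n_groups + 1).astype(int)
    groups = [(p[a:b], y[a:b]) for a, b in zip(edges[:-1], edges[1:]) if b > a]
    warning = None

    # merge groups whose expected counts vanish
    merged: list[tuple[np.ndarray, np.ndarray]] = []
    for gp, gy in groups:
        exp_pos, exp_neg = gp.sum(), (1 - gp).sum()
        if merged and (exp_pos == 0 or exp_neg == 0):
            pp, py = merged[-1]
            merged[-1] = (np.concatenate([pp, gp]), np.concatenate([py, gy]))
            warning = "merged a decile with zero expected count"
        else:
            merged.append((gp, gy))
    chi2 = 0.0
    for gp, gy in merged:
        e1, o1 = gp.sum(), gy.sum()
        e0, o0 = (1 - gp).sum(), (1 - gy).sum()
        if e1 > 0:
            chi2 += (o1 - e1) ** 2 / e1
        if e0 > 0:
            chi2 += (o0 - e0) ** 2 / e0
    df = len(merged) - 2
    if df < 1:
        return TestResult("hosmer_lemeshow", float(chi2), 1.0, "two", n=p.size, df=df,
                          warning="too few groups after merging")
    return TestResult("hosmer_lemeshow", float(chi2), chi2_upper_tail(float(chi2), df),
                      "two", n=p.size, df=df, warning=warning)
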