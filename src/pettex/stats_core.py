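"""The statistical test battery used by the cohort analysis.

Implements the procedures the workflow needs with explicit, documented
conventions: Fisher's exact test (hypergeometric enumeration, one- and
two-sided), the Mann-Whitney U test (exact enumeration for small untied
samples, tie-corrected normal approximation otherwise), the Wilcoxon signed
rank test (exact for small n, continuity- and tie-corrected normal
otherwise), Shapiro-Wilk normality, the two-way random effects absolute
agreement single-measure ICC(2,1), and the chi-square / normal tail
functions used for calibration and AUC-comparison p-values.

Sidedness conventions
---------------------
``fisher_exact`` one-sided p is the tail probability of the observed cell in
the direction of the observed association (p = 1 when the table sits exactly
at its independence expectation); the two-sided p sums the probabilities of
all tables with the observed margins that are no more likely than the
observed one. Published 2x2 CR-rate comparisons in this setting are
reproduced by the one-sided mode; both are provided.
"""

from __future__ import annotations

import dataclasses
import math
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "IccResult",
    "fisher_exact",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "shapiro_wilk",
    "icc_two_way",
    "chi2_upper_tail",
    "normal_two_sided_p",
    "feature_test_table",
]


@dataclasses.dataclass(frozen=True)
class TestResult:
    """Uniform container for a hypothesis test outcome."""

    method: str
    statistic: float
    p_value: float
    sidedness: str = "two"
    n: int | None = None
    df: int | None = None
    warning: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


ICC_BANDS = (
    (0.200, "poor"),
    (0.400, "fair"),
    (0.600, "moderate"),
    (0.800, "good"),
    (1.000, "excellent"),
)


@dataclasses.dataclass(frozen=True)
class IccResult:
    """Intraclass correlation with its qualitative agreement band."""

    icc: float
    band: str
    n_subjects: int


def _icc_band(icc: float) -> str:
    for upper, name in ICC_BANDS:
        if icc <= upper + 1e-12:
            return name
    return "excellent"


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def fisher_exact(table: Sequence[Sequence[int]], sidedness: str = "two") -> TestResult:
    """Fisher's exact test for a 2x2 table by hypergeometric enumeration.

    ``table`` is ``[[a, b], [c, d]]`` with rows = patient subgroups and
    columns = outcome (e.g. CR / non-CR). With a degenerate margin the test
    is vacuous and p = 1 is returned with a warning.
    """
    (a, b), (c, d) = table
    a, b, c, d = (int(x) for x in (a, b, c, d))
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be nonnegative")
    n = a + b + c + d
    if n < 1:
        raise ValueError("table total must be >= 1")
    r1, r2, c1 = a + b, c + d, a + c
    if sidedness not in ("one", "two"):
        raise ValueError(f"sidedness must be 'one' or 'two'; got {sidedness!r}")
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return TestResult("fisher_exact", float(a), 1.0, sidedness, n=n,
                          warning="degenerate margin; test is vacuous")

    # support of the (1,1) cell given the margins
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = float(pmf[a - lo])

    if sidedness == "two":
        p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
        if p > 1.0 - 1e-9:  # full support included: exactly 1 up to fp error
            p = 1.0
    else:
        expected = r1 * c1 / n
        if a > expected:
            p = float(pmf[support >= a].sum())
        elif a < expected:
            p = float(pmf[support <= a].sum())
        else:  # no observed association: no direction to test
            p = 1.0
    return TestResult("fisher_exact", float(a), min(p, 1.0), sidedness, n=n)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _rankdata(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    sidedness: str = "two",
    exact_max_n: int = 12,
) -> TestResult:
    """Mann-Whitney U test with 0.5 credit for ties.

    Exact enumeration of all rank assignments when the pooled sample has at
    most ``exact_max_n`` observations and no ties; tie-corrected normal
    approximation otherwise. U is reported for the first sample; the
    one-sided p is the tail probability in the direction of the observed
    shift.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)
    u1 = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size

    if n1 + n2 <= exact_max_n and not has_ties:
        # enumerate every assignment of pooled ranks to the first sample
        all_ranks = tuple(range(1, n1 + n2 + 1))
        us = np.array(
            [sum(comb) - n1 * (n1 + 1) / 2.0 for comb in combinations(all_ranks, n1)]
        )
        ge = float(np.mean(us >= u1 - 1e-9))
        le = float(np.mean(us <= u1 + 1e-9))
        p_one = min(ge, le)  # tail in the direction of the observed shift
        p = min(1.0, 2.0 * min(ge, le)) if sidedness == "two" else p_one
        method = "mann_whitney_u_exact"
        z = math.nan
    else:
        mu = n1 * n2 / 2.0
        # tie correction on the variance
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts**3 - counts)).sum())
        n = n1 + n2
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            return TestResult("mann_whitney_u_normal", u1, 1.0, sidedness, n=n,
                              warning="zero variance (all values tied)")
        z = (u1 - mu) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z)) if sidedness == "two" else float(sps.norm.sf(abs(z)))
        method = "mann_whitney_u_normal"
    return TestResult(method, u1, min(max(p, 0.0), 1.0), sidedness, n=n1 + n2)


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    sidedness: str = "two",
    exact_max_n: int = 9,
) -> TestResult:
    """Wilcoxon signed rank test for paired samples (differences x - y).

    Zero differences are dropped. Exact enumeration of all sign patterns for
    n <= ``exact_max_n``; otherwise a normal approximation with continuity
    and tie correction. The statistic reported is the signed Z (or W+ in the
    exact branch); Z < 0 means x tends to be smaller than y.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, sidedness, n=0,
                          warning="all differences are zero")
    ranks = sps.rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0

    if n <= exact_max_n:
        # all 2^n sign assignments of the observed |d| ranks
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        ge = float(np.mean(totals >= w_plus - 1e-9))
        le = float(np.mean(totals <= w_plus + 1e-9))
        p_one = ge if w_plus >= mu else le
        p = min(1.0, 2.0 * min(ge, le)) if sidedness == "two" else p_one
        return TestResult("wilcoxon_signed_rank_exact", w_plus, min(p, 1.0), sidedness, n=n)

    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return TestResult("wilcoxon_signed_rank_normal", 0.0, 1.0, sidedness, n=n,
                          warning="zero variance")
    # continuity correction toward the mean
    cc = 0.5 if w_plus != mu else 0.0
    shift = -cc if w_plus > mu else (cc if w_plus < mu else 0.0)
    z = (w_plus - mu + shift) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z)) if sidedness == "two" else float(sps.norm.sf(abs(z)))
    return TestResult("wilcoxon_signed_rank_normal", z, min(max(p, 0.0), 1.0), sidedness, n=n)


# ---------------------------------------------------------------------------
# Shapiro-Wilk, ICC, tail helpers
# ---------------------------------------------------------------------------


def shapiro_wilk(x: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (Royston's AS R94 approximation)."""
    x = np.asarray(x, dtype=np.float64)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000; got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return TestResult("shapiro_wilk", float(w), float(p), "two", n=int(x.size))


def icc_two_way(ratings: np.ndarray) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (n_subjects x n_raters) matrix with no missing cells.
    Computed from the two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    ratings = np.asarray(ratings, dtype=np.float64)
    if ratings.ndim != 2 or ratings.shape[0] < 3 or ratings.shape[1] < 2:
        raise ValueError("need >= 3 subjects and >= 2 raters")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("ratings contain missing or non-finite cells")
    n, k = ratings.shape
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((ratings - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= 0 or abs(denom) < 1e-300:
        raise ValueError("zero between-subject variance; ICC undefined")
    icc = (msr - mse) / denom
    return IccResult(float(icc), _icc_band(float(icc)), n)


def chi2_upper_tail(statistic: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if statistic < 0:
        raise ValueError(f"chi-square statistic must be >= 0; got {statistic}")
    if df < 1:
        raise ValueError(f"df must be a positive integer; got {df}")
    return float(sps.chi2.sf(statistic, df))


def normal_two_sided_p(z: float) -> float:
    """Two-sided standard-normal p-value, 2 * (1 - Phi(|z|))."""
    return float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# batch interface
# ---------------------------------------------------------------------------


def feature_test_table(features, labels, positive_label: str = "nonCR"):
    """Per-feature Mann-Whitney comparison of two outcome groups.

    ``features`` is a DataFrame (patients x features); ``labels`` a
    same-length sequence of group labels. Returns a DataFrame indexed by
    feature with columns ``p_value``, ``median_neg``, ``median_pos``,
    ``direction`` (sign of pos-group median minus neg-group median) and
    ``shapiro_p`` (normality of the pooled values; NaN when degenerate).
    """
    import pandas as pd

    labels = np.asarray(labels)
    pos = labels == positive_label
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValueError("need >= 2 patients per class")
    rows = {}
    for name in features.columns:
        col = features[name].to_numpy(dtype=np.float64)
        if np.ptp(col) == 0:
            rows[name] = dict(p_value=1.0, median_neg=float(np.median(col)),
                              median_pos=float(np.median(col)), direction=0.0,
                              shapiro_p=np.nan)
            continue
        res = mann_whitney_u(col[pos], col[~pos], sidedness="two")
        med_pos = float(np.median(col[pos]))
        med_neg = float(np.median(col[~pos]))
        try:
            sw = shapiro_wilk(col).p_value
        except ValueError:
            sw = np.nan
        rows[name] = dict(p_value=res.p_value, median_neg=med_neg, median_pos=med_pos,
                          direction=float(np.sign(med_pos - med_neg)), shapiro_p=sw)
    return pd.DataFrame.from_dict(rows, orient="index")
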