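"""Statistical layer of the severity-correlation study.

One-way ANOVA (raw samples or published-style mean/SD/n summaries), LSD
post-hoc pairwise comparisons, unweighted Cohen's kappa with the
study's interpretation bands, two-way random absolute-agreement ICC,
Tukey box-and-whisker summaries, Pearson correlation, and contingency
percentage tables.

Sample SDs use the n−1 denominator throughout; reported p-values are
two-sided; LSD comparisons are unadjusted pairwise t-tests on the
pooled ANOVA error variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import UndefinedStatisticError

KAPPA_POOR = "poor"
KAPPA_FAIR_TO_GOOD = "fair to good"
KAPPA_EXCELLENT = "excellent"


@dataclass(frozen=True)
class GroupSummary:
    """Published-style per-group summary: label, n, mean, sample SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    mse: float                 # pooled within-group mean square
    degenerate: bool = False   # zero within-variance with unequal means


@dataclass(frozen=True)
class PairwiseLSDResult:
    label_a: str
    label_b: str
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ContingencyTable:
    """r x c integer counts with row/column labels.  For the grading
    agreement analysis rows are pathological grades (L/M/H) and columns
    clinical grades (II/III/IV), matched by position."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.sum() == 0:
            raise ValueError("table total must be > 0")
        if len(self.row_labels) != arr.shape[0] or \
                len(self.col_labels) != arr.shape[1]:
            raise ValueError("label lengths must match table shape")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    category: str


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model: str = "two-way random, absolute agreement, single rater"


@dataclass(frozen=True)
class BoxplotSummary:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def _anova_from_moments(ns: np.ndarray, means: np.ndarray,
                        ss_within: float) -> AnovaResult:
    k = len(ns)
    n_total = int(ns.sum())
    df_b, df_w = k - 1, n_total - k
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    if ss_within <= 0:
        if ss_between <= 1e-300:
            return AnovaResult(0.0, df_b, df_w, 1.0, 0.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0, 0.0,
                           degenerate=True)
    mse = ss_within / df_w
    f = (ss_between / df_b) / mse
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p, float(mse))


def anova_oneway_raw(groups: list[np.ndarray | list[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA on raw per-group samples.

    Requires >= 2 groups with >= 2 observations each.  Zero
    within-group variance with unequal means yields an infinite F with
    p = 0, flagged as degenerate.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    return _anova_from_moments(ns, means, ss_within)


def anova_from_summary(summaries: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA reconstructed from mean/SD/n group summaries.

    Algebraically identical to :func:`anova_oneway_raw` when the
    summaries are computed from the raw groups:
    SS_within = sum (n_i − 1) s_i^2, SS_between from the group means
    around the weighted grand mean.
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 groups")
    for s in summaries:
        if s.n < 2:
            raise ValueError(f"group {s.label!r}: n must be >= 2")
    ns = np.array([s.n for s in summaries])
    means = np.array([s.mean for s in summaries], dtype=float)
    ss_within = float(sum((s.n - 1) * s.sd**2 for s in summaries))
    return _anova_from_moments(ns, means, ss_within)


def lsd_pairwise(summaries: list[GroupSummary], mse: float,
                 df: int) -> list[PairwiseLSDResult]:
    """Least-significant-difference pairwise comparisons.

    For each group pair: t = (m_i − m_j)/sqrt(MSE (1/n_i + 1/n_j)) with
    the pooled ANOVA error variance and df = N − k; two-sided p, no
    multiplicity adjustment (that is the LSD rule).  All k(k−1)/2 pairs
    are returned.
    """
    if mse <= 0:
        raise ValueError("mse must be > 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    out = []
    for i in range(len(summaries)):
        for j in range(i + 1, len(summaries)):
            a, b = summaries[i], summaries[j]
            diff = a.mean - b.mean
            se = np.sqrt(mse * (1.0 / a.n + 1.0 / b.n))
            t = diff / se
            p = 2.0 * float(sps.t.sf(abs(t), df))
            out.append(PairwiseLSDResult(a.label, b.label, float(diff),
                                         float(t), df, p))
    return out


def kappa_category(kappa: float) -> str:
    """Interpretation band: poor below 0.40, fair to good in
    [0.40, 0.75), excellent from 0.75 up."""
    if kappa < 0.40:
        return KAPPA_POOR
    if kappa < 0.75:
        return KAPPA_FAIR_TO_GOOD
    return KAPPA_EXCELLENT


def cohens_kappa(table: ContingencyTable) -> KappaResult:
    """Unweighted Cohen's kappa of a square contingency table.

    kappa = (Po − Pe)/(1 − Pe) with Po the diagonal mass and Pe the
    chance agreement from the marginals.  Row i corresponds to column i
    (grading systems aligned by severity order).  Pe = 1 makes kappa
    undefined and raises :class:`UndefinedStatisticError`.
    """
    arr = table.array
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("kappa requires a square table")
    n = arr.sum()
    po = float(np.trace(arr) / n)
    pe = float((arr.sum(axis=1) * arr.sum(axis=0)).sum() / n**2)
    if abs(1.0 - pe) < 1e-12:
        raise UndefinedStatisticError("expected agreement is 1; kappa undefined")
    k = (po - pe) / (1.0 - pe)
    return KappaResult(kappa=float(k), observed_agreement=po,
                       expected_agreement=pe, category=kappa_category(k))


def icc_inter_rater(ratings: np.ndarray) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single
    rater, on a subjects x raters matrix of numeric ratings.

    ICC = (MSR − MSE)/(MSR + (k−1) MSE + k (MSC − MSE)/n) from the
    standard mean-squares decomposition (n subjects, k raters).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    if ss_total < 1e-12:
        raise UndefinedStatisticError("zero total variance; ICC undefined")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return ICCResult(icc=float(icc))


def boxplot_summary(values: np.ndarray | list[float],
                    quartile_method: str = "interpolated") -> BoxplotSummary:
    """Tukey box-and-whisker summary of a sample.

    Quartiles by linear interpolation (default) or classic Tukey hinges
    (``quartile_method='tukey'``); whiskers reach the furthest data
    points within 1.5 IQR of the quartiles; points beyond the whiskers
    are listed as outliers.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("need at least one value")
    if quartile_method == "interpolated":
        q1, med, q3 = np.percentile(x, [25, 50, 75])
    elif quartile_method == "tukey":
        med = float(np.median(x))
        half = (x.size + 1) // 2
        q1 = float(np.median(x[:half]))
        q3 = float(np.median(x[-half:]))
    else:
        raise ValueError("quartile_method must be 'interpolated' or 'tukey'")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    # whiskers reach the furthest in-fence points but never retreat
    # inside the box (interpolated quartiles may exceed the data)
    whisker_low = float(min(inside.min(), q1)) if inside.size else float(q1)
    whisker_high = float(max(inside.max(), q3)) if inside.size else float(q3)
    outliers = tuple(float(v) for v in x[(x < lo_fence) | (x > hi_fence)])
    return BoxplotSummary(float(q1), float(med), float(q3),
                          whisker_low, whisker_high, outliers)


def pearson_corr(x, y) -> float:
    """Sample Pearson correlation; zero variance raises
    :class:`UndefinedStatisticError`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if x.std() < 1e-12 or y.std() < 1e-12:
        raise UndefinedStatisticError("zero variance; correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


def contingency_percentages(table: ContingencyTable
                            ) -> dict[str, np.ndarray | None | float]:
    """Row-wise cell percentages and marginal percentages, 1 d.p.

    Each cell as a percent of its row total; row and column totals as a
    percent of the grand total.  A zero row total leaves that row's
    percentages as NaN (flagged via ``zero_rows``).
    """
    arr = table.array
    total = arr.sum()
    row_totals = arr.sum(axis=1)
    col_totals = arr.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        row_pct = np.round(100.0 * arr / row_totals[:, None], 1)
    row_pct[row_totals == 0, :] = np.nan
    return {
        "row_percentages": row_pct,
        "row_marginal_percentages": np.round(100.0 * row_totals / total, 1),
        "col_marginal_percentages": np.round(100.0 * col_totals / total, 1),
        "zero_rows": [table.row_labels[i]
                      for i in np.flatnonzero(row_totals == 0)],
        "total": float(total),
    }


__all__ = [
    "AnovaResult", "BoxplotSummary", "ContingencyTable", "GroupSummary",
    "ICCResult", "KappaResult", "PairwiseLSDResult", "anova_from_summary",
    "anova_oneway_raw", "boxplot_summary", "cohens_kappa",
    "contingency_percentages", "icc_inter_rater", "kappa_category",
    "lsd_pairwise", "pearson_corr",
]
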