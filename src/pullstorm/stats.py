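"""Cohort-level inference for the two-group aggregate biomarker study.

Implements the statistics layer applied to per-participant aggregate data:

* per-participant summaries — αS/Aβ count ratio, thresholded morphology
  proportions, and the combined discriminator (ratio × proportion of Aβ
  aggregates with area > 0.03 µm² and circularity < 0.4);
* morphology threshold discovery by cumulative-distribution subtraction;
* a normality-gated two-group test decision tree (Shapiro–Wilk → Levene →
  Student/Welch t or Wilcoxon rank-sum) with Cohen's d / rank-biserial-style
  r effect sizes;
* ROC analysis with the maximum-sensitivity-plus-specificity cutoff;
* logistic regression with McFadden's pseudo-R² and likelihood-ratio χ²;
* Pearson/Kendall correlations, Pearson χ², Dunn's pairwise test.

Effect size for rank-sum tests is r = |Z| / √N with
Z = (W − n₁n₂/2) / √(n₁n₂(n₁+n₂+1)/12), W the Mann–Whitney statistic of the
first group, no continuity or tie correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "ParticipantSummary",
    "ThresholdResult",
    "GroupComparison",
    "RocResult",
    "LogisticResult",
    "MorphologyThresholds",
    "summarize_participant",
    "find_threshold",
    "compare_groups",
    "effect_size_r",
    "cohens_d_from_t",
    "roc",
    "fit_logistic",
    "correlate",
    "chi_square",
    "dunn_pairwise",
    "CohortModel",
    "CohortResults",
]

ALPHA = 0.05


@dataclass(frozen=True)
class MorphologyThresholds:
    """Fixed morphology cutoffs of the assay (Aβ area 0.03 µm², αS area
    0.02 µm², circularity 0.4 for both targets)."""

    area_um2: float = 0.03
    circularity: float = 0.4
    asyn_area_um2: float = 0.02


@dataclass
class ParticipantSummary:
    participant_id: str
    group: str
    count_asyn: int
    count_abeta: int
    ratio: float                 # count_asyn / count_abeta
    prop_area: float             # share of aggregates with area > θ_area
    prop_circ: float             # share with circularity < θ_circ
    prop_both: float             # share meeting both thresholds
    discriminator: float         # ratio × prop_both
    valid: bool = True           # False when count_abeta == 0 (ratio undefined)


@dataclass
class ThresholdResult:
    feature: str                 # "area" or "circularity"
    grid: np.ndarray
    cdf_diff: np.ndarray
    threshold: float
    direction: str               # "greater_than" (area) or "less_than" (circularity)
    max_diff: float
    degenerate: bool = False


@dataclass
class GroupComparison:
    test_used: str               # student_t | welch_t | wilcoxon
    statistic: float             # t, or Mann–Whitney W of the first sample
    df: float | None
    p_two_sided: float
    effect_size: float           # Cohen's d (t tests) or r (rank-sum)
    effect_size_kind: str
    ci95: tuple[float, float]
    gate_shapiro_p: tuple[float, float]
    gate_levene_p: float | None
    n: tuple[int, int]


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float


@dataclass
class LogisticResult:
    params: pd.Series
    bse: pd.Series
    wald_z: pd.Series
    p_values: pd.Series
    mcfadden_r2: float
    lr_chi2: float
    lr_df: int
    lr_p: float
    llf: float
    llnull: float
    separation: bool = False


# ---------------------------------------------------------------------------
# participant summaries
# ---------------------------------------------------------------------------

def summarize_participant(
    participant_id: str,
    group: str,
    count_asyn: int,
    count_abeta: int,
    abeta_morphology: pd.DataFrame,
    thresholds: MorphologyThresholds = MorphologyThresholds(),
) -> ParticipantSummary:
    """Per-participant summary of counts and Aβ morphology proportions.

    ``abeta_morphology`` must carry ``area_um2`` and ``circularity`` columns,
    one row per segmented Aβ aggregate. A participant with zero Aβ count has
    an undefined ratio and is flagged invalid (excluded from group tests).
    """
    if count_asyn < 0 or count_abeta < 0:
        raise ValueError("counts must be non-negative")
    n = len(abeta_morphology)
    if n:
        big = abeta_morphology["area_um2"].to_numpy() > thresholds.area_um2
        fib = abeta_morphology["circularity"].to_numpy() < thresholds.circularity
        prop_area = float(big.mean())
        prop_circ = float(fib.mean())
        prop_both = float((big & fib).mean())
    else:
        prop_area = prop_circ = prop_both = 0.0
    if count_abeta == 0:
        return ParticipantSummary(participant_id, group, count_asyn, count_abeta,
                                  math.nan, prop_area, prop_circ, prop_both,
                                  math.nan, valid=False)
    ratio = count_asyn / count_abeta
    return ParticipantSummary(participant_id, group, count_asyn, count_abeta,
                              ratio, prop_area, prop_circ, prop_both,
                              ratio * prop_both)


# ---------------------------------------------------------------------------
# CDF-difference morphology thresholds
# ---------------------------------------------------------------------------

def _ecdf(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    values = np.sort(values)
    return np.searchsorted(values, grid, side="right") / len(values)


def find_threshold(pooled_pd: np.ndarray, pooled_ctrl: np.ndarray,
                   feature: str = "area") -> ThresholdResult:
    """Morphology threshold from cumulative-distribution subtraction.

    The empirical CDFs of the pooled disease and control values are evaluated
    on the sorted union of observed values and subtracted; the grid point
    where the oriented difference is maximal becomes the threshold. For area
    the difference is CDF_ctrl − CDF_pd (the disease group's heavier right
    tail gives a positive peak, aggregates *larger* than the threshold are
    counted); for circularity it is CDF_pd − CDF_ctrl (the disease group's
    excess of low-circularity aggregates, counted *below* the threshold).
    Ties break toward the smallest grid value.
    """
    a = np.asarray(pooled_pd, dtype=float)
    b = np.asarray(pooled_ctrl, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both pooled samples must be non-empty")
    grid = np.unique(np.concatenate([a, b]))
    if feature == "area":
        diff = _ecdf(b, grid) - _ecdf(a, grid)
        direction = "greater_than"
    elif feature == "circularity":
        diff = _ecdf(a, grid) - _ecdf(b, grid)
        direction = "less_than"
    else:
        raise ValueError(f"unknown feature {feature!r}")
    idx = int(np.argmax(diff))  # argmax returns the first (smallest) maximizer
    return ThresholdResult(
        feature=feature, grid=grid, cdf_diff=diff,
        threshold=float(grid[idx]), direction=direction,
        max_diff=float(diff[idx]), degenerate=bool(diff[idx] <= 0),
    )


# ---------------------------------------------------------------------------
# two-group comparison decision tree
# ---------------------------------------------------------------------------

def effect_size_r(W: float, n1: int, n2: int) -> float:
    """Rank-sum effect size r = |Z| / √N.

    Z standardizes the first sample's Mann–Whitney statistic against its null
    mean n₁n₂/2 and sd √(n₁n₂(n₁+n₂+1)/12), with no continuity or tie
    correction; N = n₁ + n₂.
    """
    if not 0 <= W <= n1 * n2:
        raise ValueError("W must lie in [0, n1*n2]")
    z = (W - n1 * n2 / 2) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
    return abs(z) / math.sqrt(n1 + n2)


def cohens_d_from_t(t: float, n1: int, n2: int) -> float:
    """Cohen's d recovered from a two-sample t statistic: d = t·√(1/n₁+1/n₂)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    return t * math.sqrt(1 / n1 + 1 / n2)


def _t_ci95(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float]:
    """95% CI for the mean difference (a − b)."""
    n1, n2 = len(a), len(b)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if welch:
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    tcrit = sps.t.ppf(0.975, df)
    return (diff - tcrit * se, diff + tcrit * se)


def _hodges_lehmann_ci95(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Distribution-free 95% CI for the location shift (a − b), from the
    ordered pairwise differences and the normal approximation of U."""
    diffs = np.sort((a[:, None] - b[None, :]).ravel())
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2
    sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
    k = int(math.floor(mu - 1.96 * sd))
    k = max(k, 0)
    hi = min(len(diffs) - k, len(diffs)) - 1
    return (float(diffs[k]), float(diffs[hi]))


def compare_groups(a, b, alpha: float = ALPHA) -> GroupComparison:
    """Normality-gated two-group comparison (all tests two-tailed).

    Both samples pass Shapiro–Wilk at α → Levene's test (mean-centred): a
    significant variance difference selects Welch's t, otherwise Student's t,
    with Cohen's d. Any Shapiro–Wilk rejection selects the Wilcoxon rank-sum
    test with effect size r = |Z|/√N and a Hodges–Lehmann shift CI.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n1, n2 = len(a), len(b)
    if n1 < 3 or n2 < 3:
        raise ValueError("need at least 3 observations per group")
    sw_a = sps.shapiro(a).pvalue if np.ptp(a) > 0 else 0.0
    sw_b = sps.shapiro(b).pvalue if np.ptp(b) > 0 else 0.0

    if sw_a >= alpha and sw_b >= alpha:
        lev_p = float(sps.levene(a, b, center="mean").pvalue)
        welch = lev_p < alpha
        res = sps.ttest_ind(a, b, equal_var=not welch)
        t = float(res.statistic)
        df = float(res.df)
        d = cohens_d_from_t(t, n1, n2)
        return GroupComparison(
            test_used="welch_t" if welch else "student_t",
            statistic=t, df=df, p_two_sided=float(res.pvalue),
            effect_size=d, effect_size_kind="cohens_d",
            ci95=_t_ci95(a, b, welch),
            gate_shapiro_p=(float(sw_a), float(sw_b)), gate_levene_p=lev_p,
            n=(n1, n2),
        )

    mwu = sps.mannwhitneyu(a, b, alternative="two-sided")
    W = float(mwu.statistic)  # U of the first sample
    return GroupComparison(
        test_used="wilcoxon",
        statistic=W, df=None, p_two_sided=float(mwu.pvalue),
        effect_size=effect_size_r(W, n1, n2), effect_size_kind="r",
        ci95=_hodges_lehmann_ci95(a, b),
        gate_shapiro_p=(float(sw_a), float(sw_b)), gate_levene_p=None,
        n=(n1, n2),
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc(scores, labels) -> RocResult:
    """ROC curve, trapezoid AUC and the maximum sensitivity+specificity cutoff.

    ``labels`` are truthy for the disease class, which is scored high.
    Thresholds are the midpoints between sorted unique scores extended by
    ±∞; a case is called positive when score >= threshold. The AUC equals the
    Mann–Whitney pair statistic U/(n₁n₂) with ties counted one half. Cutoff
    ties break toward the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    ok = ~np.isnan(scores)
    scores, labels = scores[ok], labels[ok]
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(scores[labels] >= t).mean() for t in thresholds])
    spec = np.array([(scores[~labels] < t).mean() for t in thresholds])
    # AUC by trapezoid over the (1-spec, sens) curve, sorted by threshold
    fpr = 1 - spec
    order = np.argsort(thresholds)[::-1]  # from all-negative to all-positive
    auc = float(np.trapezoid(sens[order], fpr[order]))
    youden = sens + spec
    idx = int(np.argmax(youden))  # first occurrence = smallest threshold
    return RocResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc,
        optimal_cutoff=float(thresholds[idx]),
        sens_at_cutoff=float(sens[idx]), spec_at_cutoff=float(spec[idx]),
    )


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def fit_logistic(features: pd.DataFrame, labels) -> LogisticResult:
    """Maximum-likelihood logistic regression with Wald tests, McFadden's
    pseudo-R² (1 − lnL/lnL₀) and the likelihood-ratio χ² against the
    intercept-only model. Perfect separation is detected and flagged."""
    X = pd.DataFrame(features).astype(float)
    y = np.asarray(labels).astype(float)
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need more observations than parameters")
    if (X.nunique() <= 1).any():
        raise ValueError("constant feature")
    Xc = sm.add_constant(X)
    separation = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception:
        separation = True
        fit = sm.Logit(y, Xc).fit_regularized(alpha=1e-8, disp=0, maxiter=500)
    if not separation and np.abs(fit.params).max() > 50:
        separation = True
    llf = float(fit.llf)
    lln = float(sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf)
    lr = max(2 * (llf - lln), 0.0)
    df = X.shape[1]
    return LogisticResult(
        params=fit.params, bse=fit.bse, wald_z=fit.params / fit.bse,
        p_values=pd.Series(2 * sps.norm.sf(np.abs(fit.params / fit.bse)),
                           index=fit.params.index),
        mcfadden_r2=1 - llf / lln if lln != 0 else 0.0,
        lr_chi2=lr, lr_df=df, lr_p=float(sps.chi2.sf(lr, df)),
        llf=llf, llnull=lln, separation=separation,
    )


# ---------------------------------------------------------------------------
# correlations, χ², Dunn
# ---------------------------------------------------------------------------

def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson r (t-based p) or Kendall tau-b (normal-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    if method == "pearson":
        r = sps.pearsonr(x, y)
        return float(r.statistic), float(r.pvalue)
    if method == "kendall":
        r = sps.kendalltau(x, y, variant="b", method="asymptotic")
        return float(r.statistic), float(r.pvalue)
    raise ValueError(f"unknown method {method!r}")


def chi_square(table) -> tuple[float, float]:
    """Pearson's χ² on a contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def dunn_pairwise(groups: list) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons with tie correction and
    Bonferroni adjustment over all pairs."""
    if len(groups) < 3:
        raise ValueError("Dunn's test needs at least 3 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (N - 1))
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt((N * (N + 1) / 12 - tie_term) * (1 / sizes[i] + 1 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2 * sps.norm.sf(abs(z))
            rows.append({"group_i": i, "group_j": j, "z": z, "p": p,
                         "p_adjusted": min(1.0, p * n_pairs)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort model front end
# ---------------------------------------------------------------------------

class CohortModel:
    """Two-group discriminator analysis of a participant summary table.

    The table needs columns ``participant_id, group, count_asyn, count_abeta,
    prop_both`` (or per-aggregate morphology from which they were built) plus
    ``ratio`` and ``discriminator``; ``fit()`` runs the gated group
    comparisons and ROC analyses and returns a :class:`CohortResults`.
    """

    MEASURES = ("count_asyn", "count_abeta", "ratio", "prop_area", "prop_circ",
                "prop_both", "discriminator")

    def __init__(self, summaries: pd.DataFrame, disease_group: str = "PD",
                 alpha: float = ALPHA):
        req = {"participant_id", "group", "ratio", "discriminator"}
        missing = req - set(summaries.columns)
        if missing:
            raise ValueError(f"summary table missing columns: {sorted(missing)}")
        self.summaries = summaries.reset_index(drop=True)
        self.disease_group = disease_group
        self.alpha = alpha

    @classmethod
    def from_participants(cls, participants: list[ParticipantSummary], **kwargs):
        df = pd.DataFrame([vars(p) for p in participants])
        return cls(df, **kwargs)

    def fit(self) -> "CohortResults":
        df = self.summaries
        is_pd = df["group"] == self.disease_group
        comparisons, rocs = {}, {}
        for m in self.MEASURES:
            if m not in df.columns:
                continue
            a = df.loc[is_pd, m].to_numpy(dtype=float)
            b = df.loc[~is_pd, m].to_numpy(dtype=float)
            valid_a, valid_b = a[~np.isnan(a)], b[~np.isnan(b)]
            if len(valid_a) >= 3 and len(valid_b) >= 3:
                comparisons[m] = compare_groups(valid_a, valid_b, self.alpha)
                if np.ptp(np.concatenate([valid_a, valid_b])) > 0:
                    mask = ~df[m].isna()
                    rocs[m] = roc(df.loc[mask, m], is_pd[mask])
        return CohortResults(self, comparisons, rocs)


class CohortResults:
    """Fitted cohort comparison: per-measure group tests and ROC curves."""

    def __init__(self, model: CohortModel, comparisons: dict, rocs: dict):
        self.model = model
        self.comparisons = comparisons
        self.rocs = rocs

    def summary(self) -> pd.DataFrame:
        rows = []
        for m, c in self.comparisons.items():
            r = self.rocs.get(m)
            rows.append({
                "measure": m, "test": c.test_used, "statistic": c.statistic,
                "df": c.df, "p": c.p_two_sided,
                "effect_size": c.effect_size, "effect_kind": c.effect_size_kind,
                "auc": r.auc if r else math.nan,
                "cutoff": r.optimal_cutoff if r else math.nan,
                "sensitivity": r.sens_at_cutoff if r else math.nan,
                "specificity": r.spec_at_cutoff if r else math.nan,
            })
        return pd.DataFrame(rows)

    def __repr__(self) -> str:
        return f"<CohortResults: {len(self.comparisons)} measures compared>"
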