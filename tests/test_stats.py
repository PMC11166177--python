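"""Oracle tests of the cohort-statistics module."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from pullstorm.stats import (
    CohortModel,
    MorphologyThresholds,
    chi_square,
    cohens_d_from_t,
    compare_groups,
    correlate,
    dunn_pairwise,
    effect_size_r,
    find_threshold,
    fit_logistic,
    roc,
    summarize_participant,
)


# ---------------------------------------------------------------------------
# published worked values (closed-form functions of their printed inputs)
# ---------------------------------------------------------------------------

class TestPrintedEffectSizes:
    def test_r_049(self):
        assert round(effect_size_r(79, 10, 10), 2) == 0.49

    def test_r_0351(self):
        assert round(effect_size_r(118, 20, 20), 3) == 0.351

    def test_r_063(self):
        # printed as 0.63; exact value 0.6248 (rounding in the source)
        assert abs(effect_size_r(41, 17, 18) - 0.63) <= 0.006

    def test_d_values(self):
        assert round(cohens_d_from_t(2.42, 10, 10), 2) == 1.08
        # 1.345 and 1.367 are printed with sub-milli rounding slack
        # (exact values 1.34444 and 1.36765)
        assert abs(cohens_d_from_t(2.852, 9, 9) - 1.345) <= 0.002
        assert abs(cohens_d_from_t(2.901, 9, 9) - 1.367) <= 0.002
        assert round(cohens_d_from_t(2.713, 9, 9), 3) == 1.279

    def test_fold_changes(self):
        assert abs(1.07 / 0.48 - 2.2) < 0.05
        assert abs(2.18 / 1.17 - 1.9) < 0.05

    def test_r_input_validation(self):
        with pytest.raises(ValueError):
            effect_size_r(101, 10, 10)

    def test_d_input_validation(self):
        with pytest.raises(ValueError):
            cohens_d_from_t(1.0, 1, 9)


# ---------------------------------------------------------------------------
# effect size r definition
# ---------------------------------------------------------------------------

def test_effect_size_r_definition():
    W, n1, n2 = 37, 8, 11
    z = (W - n1 * n2 / 2) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
    assert effect_size_r(W, n1, n2) == pytest.approx(abs(z) / math.sqrt(n1 + n2))


def test_effect_size_r_symmetric_around_null():
    assert effect_size_r(10, 6, 7) == pytest.approx(effect_size_r(32, 6, 7))
    assert effect_size_r(6 * 7 / 2, 6, 7) == 0.0


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def _auc_oracle(scores, labels):
    """Pair-counting AUC: P(case > control) + 0.5·P(tie)."""
    cases = scores[labels]
    ctrls = scores[~labels]
    gt = (cases[:, None] > ctrls[None, :]).sum()
    eq = (cases[:, None] == ctrls[None, :]).sum()
    return (gt + 0.5 * eq) / (len(cases) * len(ctrls))


def test_roc_auc_equals_mannwhitney_u():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n1, n2 = rng.integers(3, 30, 2)
        scores = np.concatenate([rng.normal(1, 1, n1), rng.normal(0, 1, n2)])
        if rng.random() < 0.5:  # induce ties
            scores = np.round(scores)
        labels = np.concatenate([np.ones(n1, bool), np.zeros(n2, bool)])
        r = roc(scores, labels)
        assert r.auc == pytest.approx(_auc_oracle(scores, labels), abs=1e-12)


def test_roc_perfect_separation():
    r = roc(np.array([1.0, 2, 3, 10, 11, 12]),
            np.array([0, 0, 0, 1, 1, 1], bool))
    assert r.auc == 1.0
    assert 3 < r.optimal_cutoff <= 10
    assert r.sens_at_cutoff == 1.0 and r.spec_at_cutoff == 1.0


def test_roc_cutoff_tie_breaks_to_smallest():
    # two thresholds reach the same Youden index; the smaller must win
    scores = np.array([0.0, 1.0, 2.0, 3.0])
    labels = np.array([0, 0, 1, 1], bool)
    r = roc(scores, labels)
    youden = r.sensitivity + r.specificity - 1
    best = np.flatnonzero(youden == youden.max())
    assert r.optimal_cutoff == r.thresholds[best[0]] == r.thresholds[best].min()


def test_roc_sensitivity_specificity_definition():
    scores = np.array([0.1, 0.4, 0.35, 0.8])
    labels = np.array([0, 0, 1, 1], bool)
    r = roc(scores, labels)
    for t, se, sp in zip(r.thresholds, r.sensitivity, r.specificity):
        called = scores >= t
        assert se == pytest.approx((called & labels).sum() / labels.sum())
        assert sp == pytest.approx((~called & ~labels).sum() / (~labels).sum())


# ---------------------------------------------------------------------------
# CDF-subtraction threshold
# ---------------------------------------------------------------------------

def _threshold_oracle(pd_vals, ctrl_vals, feature):
    grid = np.unique(np.concatenate([pd_vals, ctrl_vals]))
    best_t, best_d = None, -np.inf
    for t in grid:  # exhaustive search, smallest-value tie break
        cdf_pd = np.mean(pd_vals <= t)
        cdf_ct = np.mean(ctrl_vals <= t)
        d = (cdf_ct - cdf_pd) if feature == "area" else (cdf_pd - cdf_ct)
        if d > best_d:
            best_t, best_d = t, d
    return best_t, best_d


@pytest.mark.parametrize("feature", ["area", "circularity"])
def test_find_threshold_matches_exhaustive_oracle(feature):
    rng = np.random.default_rng(3)
    for _ in range(50):
        a = rng.lognormal(-3.3, 0.8, rng.integers(10, 80))
        b = rng.lognormal(-3.8, 0.8, rng.integers(10, 80))
        res = find_threshold(a, b, feature)
        t0, d0 = _threshold_oracle(a, b, feature)
        assert res.threshold == pytest.approx(t0)
        assert res.max_diff == pytest.approx(d0)


def test_find_threshold_degenerate_flag():
    # identical pools: no oriented CDF difference is positive
    v = np.array([1.0, 2.0, 3.0])
    res = find_threshold(v, v, "area")
    assert res.degenerate


# ---------------------------------------------------------------------------
# gated two-group comparison
# ---------------------------------------------------------------------------

def test_compare_groups_student_t_on_normal_equal_var():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
    res = compare_groups(a, b)
    assert res.test_used == "student_t"
    t, p = sps.ttest_ind(a, b)
    assert res.statistic == pytest.approx(t)
    assert res.p_two_sided == pytest.approx(p)
    assert res.effect_size == pytest.approx(cohens_d_from_t(t, 30, 30))
    assert res.effect_size_kind == "cohens_d"
    lo, hi = res.ci95
    assert lo < np.mean(a) - np.mean(b) < hi


def test_compare_groups_welch_on_unequal_variance():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 40), rng.normal(0, 6, 40)
    res = compare_groups(a, b)
    assert res.test_used == "welch_t"
    t, p = sps.ttest_ind(a, b, equal_var=False)
    assert res.statistic == pytest.approx(t)
    assert res.p_two_sided == pytest.approx(p)


def test_compare_groups_wilcoxon_on_skewed():
    rng = np.random.default_rng(2)
    a, b = rng.lognormal(0, 1, 25), rng.lognormal(0.8, 1, 25)
    res = compare_groups(a, b)
    assert res.test_used == "wilcoxon"
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    assert res.statistic == pytest.approx(u)
    assert res.p_two_sided == pytest.approx(p, rel=0.05)
    assert res.effect_size == pytest.approx(effect_size_r(u, 25, 25))
    assert res.effect_size_kind == "r"


def test_compare_groups_nan_rejected_small_n():
    with pytest.raises(ValueError):
        compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


def test_hodges_lehmann_ci_covers_true_shift():
    rng = np.random.default_rng(5)
    cover = 0
    for _ in range(200):
        a = rng.lognormal(0, 0.5, 15) + 1.0
        b = rng.lognormal(0, 0.5, 15)
        res = compare_groups(a, b)
        if res.test_used == "wilcoxon":
            lo, hi = res.ci95
            cover += lo <= 1.0 <= hi
    assert cover >= 0.85 * 200 * 0.5  # most wilcoxon branches cover the shift


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def test_logistic_contingency_oracle():
    # 2×2 design: closed-form MLE  logit p = log(odds) per cell
    x = np.repeat([0.0, 1.0], 50)
    y = np.concatenate([np.repeat([0, 1], [35, 15]), np.repeat([0, 1], [20, 30])])
    res = fit_logistic(pd.DataFrame({"x": x}), y)
    b0 = math.log(15 / 35)
    b1 = math.log(30 / 20) - b0
    assert res.params["const"] == pytest.approx(b0, abs=1e-5)
    assert res.params["x"] == pytest.approx(b1, abs=1e-5)
    # McFadden R² from the closed-form log-likelihoods
    ll = (35 * math.log(35 / 50) + 15 * math.log(15 / 50)
          + 20 * math.log(20 / 50) + 30 * math.log(30 / 50))
    p0 = 45 / 100
    ll0 = 100 * (p0 * math.log(p0) + (1 - p0) * math.log(1 - p0))
    assert res.mcfadden_r2 == pytest.approx(1 - ll / ll0, abs=1e-5)
    assert res.lr_chi2 == pytest.approx(2 * (ll - ll0), abs=1e-4)
    assert res.lr_p == pytest.approx(sps.chi2.sf(2 * (ll - ll0), 1), abs=1e-5)
    assert not res.separation


def test_logistic_separation_flagged():
    x = np.concatenate([np.arange(10.0), np.arange(20.0, 30.0)])
    y = np.repeat([0, 1], 10)
    res = fit_logistic(pd.DataFrame({"x": x}), y)
    assert res.separation


def test_logistic_rejects_constant_feature():
    with pytest.raises(ValueError):
        fit_logistic(pd.DataFrame({"x": np.ones(20)}), np.repeat([0, 1], 10))


# ---------------------------------------------------------------------------
# correlation / chi-square / Dunn
# ---------------------------------------------------------------------------

def test_correlate_pearson_matches_scipy():
    rng = np.random.default_rng(7)
    x, y = rng.normal(size=40), rng.normal(size=40)
    r, p = correlate(x, y, "pearson")
    ref = sps.pearsonr(x, y)
    assert r == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_correlate_kendall_matches_scipy():
    rng = np.random.default_rng(8)
    x = rng.integers(0, 5, 60).astype(float)  # ties: exercises tau-b
    y = x + rng.normal(0, 1.5, 60)
    r, p = correlate(x, y, "kendall")
    ref = sps.kendalltau(x, y)
    assert r == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, rel=0.05)


def test_chi_square_matches_scipy_uncorrected():
    tab = [[12, 5], [3, 14]]
    stat, p = chi_square(tab)
    ref = sps.chi2_contingency(tab, correction=False)
    assert stat == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_dunn_pairwise_oracle():
    g = [[1.0, 2, 3, 4], [3.0, 4, 5, 6], [10.0, 11, 12, 13]]
    res = dunn_pairwise(g)
    assert len(res) == 3
    pooled = np.concatenate(g)
    ranks = sps.rankdata(pooled)
    m = [ranks[:4].mean(), ranks[4:8].mean(), ranks[8:].mean()]
    N = 12
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum() / (12 * (N - 1))
    se = math.sqrt((N * (N + 1) / 12 - tie) * (1 / 4 + 1 / 4))
    z01 = (m[0] - m[1]) / se
    row = res[(res.group_i == 0) & (res.group_j == 1)].iloc[0]
    assert row.z == pytest.approx(z01)
    assert row.p_adjusted == pytest.approx(min(1, 2 * sps.norm.sf(abs(z01)) * 3))


# ---------------------------------------------------------------------------
# participant summary + model front end
# ---------------------------------------------------------------------------

def _morph(areas, circs):
    return pd.DataFrame({"area_um2": areas, "circularity": circs})


def test_summarize_participant_proportions():
    m = _morph([0.05, 0.05, 0.01, 0.05], [0.3, 0.8, 0.3, 0.35])
    s = summarize_participant("p1", "PD", 30, 12, m)
    assert s.ratio == pytest.approx(2.5)
    assert s.prop_area == pytest.approx(3 / 4)   # area > 0.03
    assert s.prop_circ == pytest.approx(3 / 4)   # circularity < 0.4
    assert s.prop_both == pytest.approx(2 / 4)   # both
    assert s.discriminator == pytest.approx(2.5 * 0.5)
    assert s.valid


def test_summarize_participant_zero_abeta_invalid():
    s = summarize_participant("p2", "control", 10, 0, _morph([], []))
    assert not s.valid
    assert math.isnan(s.ratio) and math.isnan(s.discriminator)


def test_summarize_participant_threshold_strictness():
    # boundary values do not qualify: area must be > θ, circularity < θ
    m = _morph([0.03], [0.4])
    s = summarize_participant("p3", "PD", 5, 5, m,
                              MorphologyThresholds(0.03, 0.4, 0.02))
    assert s.prop_area == 0.0 and s.prop_circ == 0.0 and s.prop_both == 0.0


def test_cohort_model_fit_and_summary():
    rng = np.random.default_rng(11)
    rows = []
    for g, loc in (("PD", 1.0), ("control", 0.5)):
        for i in range(10):
            ratio = rng.lognormal(math.log(loc), 0.4)
            pb = rng.beta(3, 20) if g == "control" else rng.beta(6, 20)
            rows.append({"participant_id": f"{g}{i}", "group": g,
                         "count_asyn": int(rng.poisson(100 * ratio)),
                         "count_abeta": int(rng.poisson(100)), "ratio": ratio,
                         "prop_area": pb, "prop_circ": pb, "prop_both": pb,
                         "discriminator": ratio * pb})
    res = CohortModel(pd.DataFrame(rows)).fit()
    assert set(res.comparisons) == set(CohortModel.MEASURES)
    tab = res.summary()
    assert {"measure", "test", "p", "effect_size", "auc", "cutoff"} <= set(tab.columns)
    assert ((tab["auc"] >= 0) & (tab["auc"] <= 1)).all()
    # ratio contrast was generated upward for PD: AUC above chance
    assert res.rocs["ratio"].auc > 0.5


def test_cohort_model_requires_columns():
    with pytest.raises(ValueError):
        CohortModel(pd.DataFrame({"participant_id": ["a"], "group": ["PD"]}))
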