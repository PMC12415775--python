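import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrlink.biomarker_eval import (
    adjust_pvalues,
    combine_markers,
    eta_squared_h,
    evaluate_taxon,
    kruskal_wallis,
    kw_power_simulation,
    optimal_cutoff_confusion,
    pearson_r,
    roc_auc,
)
from mrlink.synthetic_data import simulate_cohort


# -------------------------------------------------------------- Kruskal-Wallis

def test_kw_hand_ranked_oracle():
    """{1,2,3} vs {4,5,6} vs {7,8,9}: H = 12/(9·10)·(2²+5²+8²)·3 − 30 = 7.2."""
    values = np.arange(1, 10)
    groups = np.repeat(["a", "b", "c"], 3)
    res = kruskal_wallis(values, groups)
    assert res.statistic == pytest.approx(7.2, abs=1e-12)
    assert res.df == 2


def test_kw_degenerate_all_equal():
    res = kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
    assert res.statistic == 0.0 and res.pval == 1.0


def test_kw_requires_two_nonempty_groups():
    with pytest.raises(ValueError):
        kruskal_wallis([1, 2, 3], ["a", "a", "a"])


def test_kw_monotone_transform_invariance():
    rng = np.random.default_rng(1)
    vals = rng.lognormal(0, 1, 30)
    groups = np.repeat(["a", "b", "c"], 10)
    h1 = kruskal_wallis(vals, groups).statistic
    h2 = kruskal_wallis(np.log(vals), groups).statistic
    h3 = kruskal_wallis(vals**3, groups).statistic
    assert h1 == pytest.approx(h2, rel=1e-12)
    assert h1 == pytest.approx(h3, rel=1e-12)


def test_kw_null_calibration():
    rng = np.random.default_rng(0)
    groups = np.repeat(["a", "b", "c"], 25)
    n = 400
    rej = sum(kruskal_wallis(rng.normal(size=75), groups).pval < 0.05 for _ in range(n))
    assert abs(rej / n - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)


# ------------------------------------------------------------------- eta² (H)

def test_eta_squared_arithmetic():
    assert eta_squared_h(7.2, 3, 9) == pytest.approx((7.2 - 2) / 6)
    assert eta_squared_h(2.0, 3, 100) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        eta_squared_h(1.0, 3, 3)


def test_eta_squared_null_mean_near_zero():
    """Under the null E[H] = k−1, so the effect size centers on 0."""
    rng = np.random.default_rng(2)
    groups = np.repeat(["a", "b", "c"], 40)
    vals = [eta_squared_h(kruskal_wallis(rng.normal(size=120), groups).statistic, 3, 120)
            for _ in range(300)]
    assert abs(float(np.mean(vals))) < 0.01


# ----------------------------------------------------------------- adjustment

def test_adjustment_hand_computations():
    np.testing.assert_allclose(
        adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh_fdr"), [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(adjust_pvalues([0.004, 0.5, 0.9], "bonferroni")[0], 0.012)
    assert adjust_pvalues([0.3], "bonferroni")[0] == 0.3
    assert adjust_pvalues([0.3], "bh_fdr")[0] == 0.3


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
def test_adjustment_monotone_and_bonferroni_dominates(pvals):
    p = np.asarray(pvals)
    bonf = adjust_pvalues(p, "bonferroni")
    bh = adjust_pvalues(p, "bh_fdr")
    assert np.all(bonf >= p - 1e-15) and np.all(bh >= p - 1e-15)
    assert np.all(bonf >= bh - 1e-12)
    assert np.all(bonf <= 1) and np.all(bh <= 1)


def test_adjustment_rejects_bad_input():
    with pytest.raises(ValueError):
        adjust_pvalues([0.5, 1.5])
    with pytest.raises(ValueError):
        adjust_pvalues([0.5], method="holm")


# -------------------------------------------------------------------- ROC/AUC

def test_auc_perfect_separation():
    scores = [1, 2, 3, 10, 11, 12]
    labels = [0, 0, 0, 1, 1, 1]
    _, auc, ci = roc_auc(scores, labels, n_boot=100, seed=0)
    assert auc == 1.0


def test_auc_equals_pair_counting_oracle_with_ties():
    rng = np.random.default_rng(3)
    scores = rng.integers(0, 5, 10).astype(float)  # ties guaranteed
    labels = np.array([0, 1, 0, 1, 1, 0, 0, 1, 1, 0])
    _, auc, _ = roc_auc(scores, labels, n_boot=50, seed=0)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)


def test_auc_symmetry_under_score_negation():
    rng = np.random.default_rng(4)
    scores = rng.normal(size=40)
    labels = rng.integers(0, 2, 40)
    labels[:2] = [0, 1]
    _, a1, _ = roc_auc(scores, labels, n_boot=50, seed=0)
    _, a2, _ = roc_auc(-scores, labels, n_boot=50, seed=0)
    assert a1 + a2 == pytest.approx(1.0, abs=1e-12)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([1, 2, 3], [1, 1, 1])


def test_auc_ci_is_deterministic_and_ordered():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=50) + np.repeat([0, 1], 25)
    labels = np.repeat([0, 1], 25)
    _, auc, ci1 = roc_auc(scores, labels, n_boot=200, seed=11)
    _, _, ci2 = roc_auc(scores, labels, n_boot=200, seed=11)
    assert ci1 == ci2
    assert ci1[0] <= auc <= ci1[1]


# ------------------------------------------------------------ cutoff/confusion

def test_cutoff_perfect_separation():
    rep = optimal_cutoff_confusion([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1],
                                   n_boot=50, seed=0)
    assert rep.sensitivity == rep.specificity == rep.accuracy == 1.0
    assert rep.direction == "risk"


def test_cutoff_matches_exhaustive_sweep_oracle():
    scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2])
    labels = np.array([0, 0, 1, 1, 1, 0])
    rep = optimal_cutoff_confusion(scores, labels, n_boot=50, seed=0)
    best = (-np.inf, None)
    for cut in np.unique(scores):
        pred = scores >= cut
        sens = np.sum(pred & (labels == 1)) / labels.sum()
        spec = np.sum(~pred & (labels == 0)) / (len(labels) - labels.sum())
        j = sens + spec - 1
        if j > best[0]:
            best = (j, cut, sens, spec)
    assert rep.cutoff == pytest.approx(best[1])
    assert rep.sensitivity == pytest.approx(best[2])
    assert rep.specificity == pytest.approx(best[3])


def test_cutoff_protective_marker_direction():
    """Lower scores in cases: direction auto-detected, classified with ≤."""
    rep = optimal_cutoff_confusion([10, 11, 12, 1, 2, 3], [0, 0, 0, 1, 1, 1],
                                   n_boot=50, seed=0)
    assert rep.direction == "protective"
    assert rep.accuracy == 1.0


def test_cutoff_constant_scores_warns():
    with pytest.warns(UserWarning, match="constant scores"):
        rep = optimal_cutoff_confusion([1.0] * 6, [0, 0, 0, 1, 1, 1], n_boot=50, seed=0)
    assert rep.extra["youden_j"] == pytest.approx(0.0)


def test_confusion_identities_on_random_fixtures():
    rng = np.random.default_rng(6)
    for _ in range(10):
        n = int(rng.integers(8, 30))
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        rep = optimal_cutoff_confusion(scores, labels, n_boot=20, seed=0)
        tn, fp = rep.confusion[0]
        fn, tp = rep.confusion[1]
        assert tn + fp + fn + tp == n
        assert rep.accuracy == pytest.approx((tp + tn) / n)


# ----------------------------------------------------------- marker combination

def test_combined_logistic_matches_statsmodels_oracle():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(8, 2))
    y = np.array([0, 0, 1, 0, 1, 1, 0, 1])
    _, rep = combine_markers(x, y, seed=0, n_boot=50)
    oracle = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    np.testing.assert_allclose(rep.extra["coefficients"], oracle.params, atol=1e-6)


def test_duplicated_marker_keeps_single_marker_auc():
    rng = np.random.default_rng(8)
    marker = rng.normal(size=40) + np.repeat([0, 1.2], 20)
    labels = np.repeat([0, 1], 20)
    _, single, _ = roc_auc(marker, labels, n_boot=20, seed=0)
    _, rep = combine_markers(np.column_stack([marker, marker]), labels,
                             seed=0, n_boot=20)
    assert rep.auc == pytest.approx(single, abs=1e-9)


def test_combination_not_worse_than_informative_marker():
    rng = np.random.default_rng(9)
    labels = np.repeat([0, 1], 40)
    informative = rng.normal(size=80) + labels * 1.5
    noise = rng.normal(size=80)
    _, single, _ = roc_auc(informative, labels, n_boot=20, seed=0)
    _, rep = combine_markers(np.column_stack([informative, noise]), labels,
                             seed=0, n_boot=20)
    assert rep.auc >= single - 0.05


def test_separation_flagged():
    x = np.column_stack([np.arange(8.0), np.ones(8)])
    y = (np.arange(8) >= 4).astype(int)
    _, rep = combine_markers(x, y, seed=0, n_boot=20)
    assert rep.extra["separation"] or rep.extra["converged"]
    assert rep.auc == 1.0


# -------------------------------------------------------------------- Pearson

def test_pearson_exact_lines():
    x = np.array([1.0, 2, 3, 4, 5])
    assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
    assert pearson_r(x, -x)[0] == pytest.approx(-1.0)


def test_pearson_six_point_hand_oracle():
    x = np.array([1.0, 2, 3, 4, 5, 6])
    y = np.array([2.0, 1, 4, 3, 7, 5])
    r, p = pearson_r(x, y)
    expected = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
    assert r == pytest.approx(float(expected), abs=1e-12)
    from scipy import stats
    t = r * np.sqrt(4 / (1 - r**2))
    assert p == pytest.approx(float(2 * stats.t.sf(abs(t), 4)), abs=1e-12)


def test_pearson_zero_variance_rejected():
    with pytest.raises(ValueError):
        pearson_r([1, 1, 1], [1, 2, 3])


# ----------------------------------------------------------------------- power

def test_power_null_is_alpha_and_saturates():
    medians = {"HC": 0.01, "PD-NC": 0.01, "PDD": 0.01}
    sizes = {"HC": 28, "PD-NC": 20, "PDD": 27}
    power, se = kw_power_simulation(medians, sizes, n_reps=300, seed=0)
    assert abs(power - 0.05) < 3 * se + 0.01
    big = {"HC": 0.0001, "PD-NC": 0.01, "PDD": 1.0}
    power_big, _ = kw_power_simulation(big, sizes, sigma_log=0.3, n_reps=100, seed=0)
    assert power_big > 0.99


# ----------------------------------------------------------------- full report

def test_evaluate_taxon_report_fields():
    cohort = simulate_cohort(seed=1)
    rep = evaluate_taxon(cohort.df, "Subdoligranulum", power_reps=100,
                         n_boot=100, seed=0)
    assert 0 <= rep["auc"] <= 1
    assert rep["auc_ci_low"] <= rep["auc"] <= rep["auc_ci_high"]
    assert 0 <= rep["power"] <= 1
    assert rep["pearson_r_mmse"] < 0  # generator plants a negative MMSE link
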