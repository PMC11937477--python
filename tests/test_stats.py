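"""Statistics battery: printed-value anchors, brute-force oracles, properties."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from bronchowall import stats as bs


# ---------------------------------------------------------------------------
# Clopper-Pearson


def test_clopper_pearson_printed_values():
    """15/15 prints 78-100%; 12/15 prints 52-96%."""
    lo, hi = bs.clopper_pearson(15, 15)
    assert round(100 * lo) == 78 and hi == 1.0
    lo, hi = bs.clopper_pearson(12, 15)
    assert round(100 * lo) == 52 and round(100 * hi) == 96


def test_clopper_pearson_boundary_closed_forms():
    lo, hi = bs.clopper_pearson(0, 15)
    assert lo == 0.0
    assert hi == pytest.approx(1.0 - 0.025 ** (1.0 / 15.0), rel=1e-12)
    lo, hi = bs.clopper_pearson(15, 15)
    assert lo == pytest.approx(0.025 ** (1.0 / 15.0), rel=1e-12)


@pytest.mark.parametrize("k,n", [(0, 5), (3, 7), (10, 20), (19, 20)])
def test_clopper_pearson_contains_estimate(k, n):
    lo, hi = bs.clopper_pearson(k, n)
    assert lo <= k / n <= hi


def test_clopper_pearson_width_shrinks_with_n():
    widths = []
    for n in (10, 40, 160, 640):
        lo, hi = bs.clopper_pearson(int(0.8 * n), n)
        widths.append(hi - lo)
    assert all(b < a for a, b in zip(widths, widths[1:]))


def test_clopper_pearson_invalid_counts():
    with pytest.raises(ValueError):
        bs.clopper_pearson(5, 4)
    with pytest.raises(ValueError):
        bs.clopper_pearson(-1, 4)


# ---------------------------------------------------------------------------
# group comparisons


def test_t_test_from_printed_summary_stats():
    """(15, 74+/-12) vs (15, 49+/-14): t ~ 5.25, df 28, p < 0.001."""
    gc = bs.compare_groups_continuous(summary_a=(15, 74, 12), summary_b=(15, 49, 14))
    assert gc.statistic == pytest.approx(5.25, abs=0.01)
    assert gc.df == 28
    assert gc.p_value < 0.001


def test_t_test_identical_groups():
    a = np.arange(10.0)
    gc = bs.compare_groups_continuous(a, a.copy(), gate=False)
    assert gc.statistic == pytest.approx(0.0, abs=1e-12)
    assert gc.p_value == pytest.approx(1.0)


def test_t_test_closed_form_oracle():
    """(n=5, mean 10, sd 1) vs (n=5, mean 12, sd 1): hand-computed pooled t."""
    gc = bs.compare_groups_continuous(summary_a=(5, 10, 1), summary_b=(5, 12, 1))
    se = math.sqrt(1.0 * (1 / 5 + 1 / 5))  # pooled variance is exactly 1
    t_oracle = (10 - 12) / se
    p_oracle = 2.0 * sps.t.sf(abs(t_oracle), 8)
    assert gc.statistic == pytest.approx(t_oracle, rel=1e-12)
    assert gc.p_value == pytest.approx(p_oracle, rel=1e-12)


def test_t_test_type_one_error_calibration():
    """Empirical alpha at 0.05 within [0.03, 0.07] over 2000 null simulations."""
    rej = 0
    for s in range(2000):
        rng = np.random.default_rng(s)
        gc = bs.compare_groups_continuous(
            rng.normal(0, 1, 15), rng.normal(0, 1, 15), gate=False
        )
        rej += gc.p_value < 0.05
    assert 0.03 <= rej / 2000 <= 0.07


def test_categorical_sex_ratio_from_cohort_table():
    """Men/women 1/14 in both groups: Fisher p = 1.00."""
    res = bs.compare_groups_categorical([[1, 14], [1, 14]])
    assert res.test == "fisher"
    assert res.p_value == pytest.approx(1.0)


def test_categorical_perfect_association():
    res = bs.compare_groups_categorical([[10, 0], [0, 10]])
    assert res.p_value < 0.001


def test_fisher_matches_hypergeometric_enumeration():
    """Two-sided Fisher p for [[14,1],[7,8]] from brute-force table enumeration."""
    table = [[14, 1], [7, 8]]
    r1, r2 = 15, 15
    c1 = 21
    n = 30

    def pmf(a):
        return (
            math.comb(c1, a) * math.comb(n - c1, r1 - a) / math.comb(n, r1)
        )

    p_obs = pmf(14)
    p_oracle = sum(pmf(a) for a in range(max(0, c1 - r2), min(r1, c1) + 1) if pmf(a) <= p_obs * (1 + 1e-9))
    res = bs.compare_groups_categorical(table)
    assert res.test == "fisher"
    assert res.p_value == pytest.approx(p_oracle, rel=1e-9)


def test_categorical_empty_margin_raises():
    with pytest.raises(ValueError):
        bs.compare_groups_categorical([[0, 0], [3, 4]])


# ---------------------------------------------------------------------------
# normality gating


def test_shapiro_gate_normal_sample_untouched():
    rng = np.random.default_rng(3)
    vals = rng.normal(50, 5, 50)
    res = bs.shapiro_gate_transform(vals)
    assert not res.transformed
    assert np.array_equal(res.values, vals)


def test_shapiro_gate_lognormal_sample_transformed():
    rng = np.random.default_rng(4)
    vals = np.exp(rng.normal(3, 1, 50))
    res = bs.shapiro_gate_transform(vals)
    assert res.transformed
    assert res.geometric_mean == pytest.approx(np.exp(np.log(vals).mean()), rel=1e-9)


def test_shapiro_gate_needs_three_values():
    with pytest.raises(ValueError):
        bs.shapiro_gate_transform([1.0, 2.0])


def test_shapiro_gate_nonpositive_with_skew_raises():
    rng = np.random.default_rng(5)
    vals = np.exp(rng.normal(0, 1.5, 60)) - 1.5  # heavy skew, some negatives
    with pytest.raises(ValueError):
        bs.shapiro_gate_transform(vals)


# ---------------------------------------------------------------------------
# ROC / Youden


def test_roc_youden_paper_operating_point():
    """All 15 positives above the cutoff, 12/15 negatives below: 100%/80%, J=0.8."""
    pos = np.arange(58.0, 73.0)
    neg = np.concatenate([np.arange(37.0, 49.0), [60.0, 63.0, 66.0]])
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(15, int), np.zeros(15, int)])
    roc = bs.roc_youden(scores, labels)
    assert roc.sensitivity == pytest.approx(1.0)
    assert roc.specificity == pytest.approx(0.8)
    assert roc.youden_j == pytest.approx(0.8)
    assert round(100 * roc.sensitivity_ci[0]) == 78
    assert round(100 * roc.specificity_ci[0]) == 52
    assert round(100 * roc.specificity_ci[1]) == 96


def test_roc_perfect_separation_auc_one():
    scores = np.array([1, 2, 3, 10, 11, 12], dtype=float)
    labels = np.array([0, 0, 0, 1, 1, 1])
    roc = bs.roc_youden(scores, labels)
    assert roc.auc == pytest.approx(1.0)
    assert roc.youden_j == pytest.approx(1.0)


def test_roc_auc_equals_pairwise_concordance_oracle():
    """AUC equals the brute-force Mann-Whitney count (ties = 1/2) on random data."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(10, 60))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            continue
        roc = bs.roc_youden(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        oracle = np.mean(
            [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
        )
        assert roc.auc == pytest.approx(oracle, abs=1e-12)


def test_roc_tie_breaks_to_lowest_cutoff():
    scores = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array([0, 1, 0, 1])
    roc = bs.roc_youden(scores, labels)
    # J = 0.5 at cutoffs 2 and 4; the lower cutoff (higher sensitivity) wins
    assert roc.cutoff == 2.0
    assert roc.sensitivity == pytest.approx(1.0)


def test_roc_single_class_raises():
    with pytest.raises(ValueError):
        bs.roc_youden([1.0, 2.0], [1, 1])


# ---------------------------------------------------------------------------
# stepwise logistic


def test_stepwise_selects_informative_predictor():
    """OR 1.1/unit signal among 4 noise predictors at n=2000 is found."""
    rng = np.random.default_rng(1)
    n = 2000
    x = rng.normal(60, 12, n)
    noise = {f"noise{i}": rng.normal(size=n) for i in range(4)}
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-(-7.0 + np.log(1.1) * x))))
    rep = bs.stepwise_logistic(y, {"biomarker": x, **noise})
    assert rep.selected == ["biomarker"]
    or_est, lo, hi = rep.odds_ratios["biomarker"]
    assert lo <= 1.1 <= hi


def test_stepwise_all_noise_empty_selection_rate():
    """Empty-model rate matches the binomial oracle 0.95^4 = 0.815.

    Forward selection over 4 independent noise candidates enters at least
    one with probability 1 - 0.95^4; the observed fraction over 100 fixed
    replicates must be consistent with that (3-sigma binomial band).
    """
    empty = 0
    for s in range(100):
        rng = np.random.default_rng(100 + s)
        preds = {f"x{i}": rng.normal(size=500) for i in range(4)}
        y = rng.binomial(1, 0.3, 500)
        rep = bs.stepwise_logistic(y, preds)
        empty += not rep.selected
    p = 0.95**4
    sd = math.sqrt(p * (1 - p) / 100)
    assert abs(empty / 100 - p) < 3 * sd


def test_stepwise_constant_outcome_raises():
    with pytest.raises(ValueError):
        bs.stepwise_logistic(np.ones(20), {"x": np.random.default_rng(0).normal(size=20)})


# ---------------------------------------------------------------------------
# Pearson correlation


def test_pearson_exact_cases():
    x = np.arange(10.0)
    r, p = bs.pearson_corr(x, x)
    assert r == pytest.approx(1.0)
    r, p = bs.pearson_corr(x, -x + 1e-9 * np.random.default_rng(0).normal(size=10))
    assert r == pytest.approx(-1.0, abs=1e-6)
    with pytest.raises(ValueError):
        bs.pearson_corr(x, np.zeros(10))


def test_pearson_generator_round_trip():
    """Synthetic cohort with r = -0.54 recovers the coefficient within 0.03."""
    from bronchowall.cohort import CohortSpec, generate_cohort

    spec = CohortSpec(n_per_group=10000, seed=9)
    spec.correlations["fev1_pp"] = -0.54
    df = generate_cohort(spec)
    sev = df[df.group == "severe"]
    r, _ = bs.pearson_corr(sev.brwall_t2_mis, sev.fev1_pp)
    assert abs(r - (-0.54)) < 0.03


# ---------------------------------------------------------------------------
# ICC / Bland-Altman


def test_icc_identical_raters():
    x = np.tile(np.arange(10.0)[:, None], (1, 2))
    rep = bs.icc_absolute(x)
    assert rep.icc == pytest.approx(1.0)
    assert rep.icc_label == "almost perfect"


def test_icc_labels_follow_printed_bands():
    assert bs.icc_category(0.97) == "almost perfect"
    assert bs.icc_category(0.9) == "very good"
    assert bs.icc_category(0.7) == "good"
    assert bs.icc_category(0.5) == "moderate"
    assert bs.icc_category(0.3) == "fair"
    assert bs.icc_category(0.1) == "slight"
    assert bs.icc_category(0.0) == "null"


def test_icc_matches_hand_computed_mean_squares():
    """6x2 table: ICC(A,1) from explicit ANOVA mean squares."""
    x = np.array([[9, 2], [1, 10], [8, 9], [2, 6], [10, 6], [4, 8.0]])
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = (
        ((x - grand) ** 2).sum()
        - (n - 1) * msr
        - (k - 1) * msc
    ) / ((n - 1) * (k - 1))
    oracle = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    rep = bs.icc_absolute(x)
    assert rep.icc == pytest.approx(oracle, rel=1e-12)


def test_icc_matches_pingouin_reference():
    """Cross-check ICC(A,1) against pingouin's mixed-model implementation."""
    pg = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(2)
    subj = rng.normal(70, 10, 12)
    x = np.column_stack([subj + rng.normal(0, 1.5, 12), subj + 0.5 + rng.normal(0, 1.5, 12)])
    mine = bs.icc_absolute(x)
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile([0, 1], 12),
            "y": x.ravel(),
        }
    )
    ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="y")
    ref_val = float(ref[ref.Type == "ICC(A,1)"].ICC.iloc[0])
    assert mine.icc == pytest.approx(ref_val, abs=1e-9)


def test_icc_requires_enough_data():
    with pytest.raises(ValueError):
        bs.icc_absolute(np.ones((4, 2)))
    with pytest.raises(ValueError):
        bs.icc_absolute(np.ones((6, 1)))


def test_bland_altman_identical():
    rep = bs.bland_altman([1.0, 2, 3, 4], [1.0, 2, 3, 4])
    assert rep.mean_difference == 0.0
    assert rep.loa == (0.0, 0.0)


def test_bland_altman_alternating_differences_oracle():
    """Differences {1,-1,1,-1}: mean 0, LoA = +/- 1.96 * sd(ddof=1)."""
    a = np.array([1.0, -1.0, 1.0, -1.0])
    rep = bs.bland_altman(a, np.zeros(4))
    sd = np.std(a, ddof=1)
    assert rep.mean_difference == pytest.approx(0.0)
    assert rep.loa[1] == pytest.approx(1.96 * sd, rel=1e-12)


def test_bland_altman_constant_offset():
    a = np.array([1.0, 2.0, 3.0])
    rep = bs.bland_altman(a, a + 2.0)
    assert rep.mean_difference == pytest.approx(-2.0)
    assert rep.loa == pytest.approx((-2.0, -2.0))


def test_bland_altman_length_mismatch():
    with pytest.raises(ValueError):
        bs.bland_altman([1.0, 2.0], [1.0])


# ---------------------------------------------------------------------------
# quartile ANOVA


def test_quartile_anova_identical_groups():
    grouping = np.repeat([1.0, 2.0, 3.0, 4.0], 10)
    response = np.tile(np.random.default_rng(0).normal(size=10), 4)
    rep = bs.quartile_anova(grouping, response)
    assert rep.f_statistic == pytest.approx(0.0, abs=1e-10)
    assert all(p > 0.99 for p in rep.tukey.values())


def test_quartile_anova_rank_arithmetic():
    """Values 1..20 grouped by their own quartiles: group means {3, 8, 13, 18}."""
    vals = np.arange(1, 21, dtype=float)
    rep = bs.quartile_anova(vals, vals)
    assert rep.group_means == pytest.approx([3.0, 8.0, 13.0, 18.0])
    assert rep.group_sizes == [5, 5, 5, 5]


def test_quartile_anova_detects_shifted_group():
    rng = np.random.default_rng(11)
    grouping = np.concatenate([rng.normal(g, 0.1, 10) for g in range(4)])
    response = rng.normal(0, 1, 40)
    response[grouping > 2.5] += 3.0  # top quartile shifted by 3 sigma
    rep = bs.quartile_anova(grouping, response)
    assert rep.p_value < 0.01
    assert rep.tukey[(0, 3)] < 0.05 and rep.tukey[(1, 3)] < 0.05 and rep.tukey[(2, 3)] < 0.05


def test_quartile_anova_massive_ties_raise():
    with pytest.raises(ValueError):
        bs.quartile_anova(np.ones(20), np.arange(20.0))


# ---------------------------------------------------------------------------
# full-layer parameter recovery


def test_stats_layer_recovers_generator_parameters():
    """Group means and target correlations recovered from a generated cohort.

    Tolerances follow the sampling SDs at the simulated n: the mean's SE is
    sd/sqrt(n), the correlation's SE is about (1-r^2)/sqrt(n).
    """
    from bronchowall.cohort import CohortSpec, generate_cohort

    n = 2000
    df = generate_cohort(CohortSpec(n_per_group=n, seed=13))
    sev = df[df.group == "severe"]
    non = df[df.group == "non-severe"]
    gc = bs.compare_groups_continuous(
        sev.brwall_t2_mis.to_numpy(), non.brwall_t2_mis.to_numpy(), gate=False
    )
    assert gc.mean[0] == pytest.approx(74.0, abs=2.0)
    assert gc.mean[1] == pytest.approx(49.0, abs=2.0)
    assert gc.p_value < 1e-10
    r, _ = bs.pearson_corr(sev.brwall_t2_mis, sev.fev1_pp)
    assert r == pytest.approx(-0.53, abs=0.05)
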